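"""Cross-omic integration: activity ratios, concordance, and limitation calls.

Given per-sample species shares of the metatranscriptome (A^T) and
metaproteome (A^P), this module computes

* the transcript:protein activity ratio rho = A^T / A^P per (species, sample)
  — a taxon-specific detection bias that in the study spanned ~100-fold and was
  stable over succession;
* fold changes of replicate-mean shares between consecutive sampling days, and
  an OLS regression of log2 protein fold change on log2 transcript fold change
  (concordance of the two omics on *within-species* dynamics);
* marker-gene time series (replicate mean with t-based 95% CI per day);
* nutrient-limitation signatures: the phosphate-starvation score
  P_score = log2(transporter expression at the final day / first day), using
  each species' highest-affinity transporter family (pstS > yjbB > pitA), and
  the nitrogen-coupling class of the amt/glnA pair (coupled, decoupled, or
  low_expression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .capability_engine import CapabilityMatrix, P_TRANSPORTER_HIERARCHY
from .genome_catalog import MemberGenome
from .transcript_quant import RPKMMatrix, day_replicate_groups, replicate_summary


@dataclass
class ConcordanceFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    scale: str


def activity_ratio(transcript_shares: pd.DataFrame, protein_shares: pd.DataFrame) -> pd.DataFrame:
    """Elementwise rho = A^T / A^P; NaN where the protein share is zero."""
    t = transcript_shares.sort_index()
    p = protein_shares.sort_index()
    if list(t.columns) != list(p.columns) or list(t.index) != list(p.index):
        raise ValueError("transcript and protein share tables must cover the same genomes and samples")
    return t / p.where(p > 0)


def day_mean_shares(shares: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean shares per day (columns ordered by day)."""
    groups = day_replicate_groups(samples)
    return pd.DataFrame({day: shares[cols].mean(axis=1) for day, cols in groups.items()})


def sequential_fold_changes(
    shares: pd.DataFrame, samples: pd.DataFrame, omic: str = "transcript"
) -> pd.DataFrame:
    """Fold change of replicate-mean shares between consecutive sampled days.

    Returns a tidy frame (genome_id, day_from, day_to, fc, omic); FC is NaN
    where either endpoint's mean share is zero.
    """
    means = day_mean_shares(shares, samples)
    days = list(means.columns)
    if len(days) < 2:
        raise ValueError("need at least two time points for fold changes")
    records = []
    for d0, d1 in zip(days, days[1:]):
        a, b = means[d0], means[d1]
        fc = b / a.where(a > 0)
        fc = fc.where(b > 0)
        for genome_id, value in fc.items():
            records.append(
                {"genome_id": genome_id, "day_from": d0, "day_to": d1,
                 "fc": float(value) if pd.notna(value) else np.nan, "omic": omic}
            )
    return pd.DataFrame(records)


def pair_fold_changes(fc_transcript: pd.DataFrame, fc_protein: pd.DataFrame) -> pd.DataFrame:
    """Merge transcript/protein fold-change records on (genome, interval)."""
    merged = fc_transcript.merge(
        fc_protein, on=["genome_id", "day_from", "day_to"], suffixes=("_t", "_p")
    )
    return merged.rename(columns={"fc_t": "fc_t", "fc_p": "fc_p"})[
        ["genome_id", "day_from", "day_to", "fc_t", "fc_p"]
    ]


def concordance_regression(
    fc_t: Sequence[float], fc_p: Sequence[float], scale: str = "log2"
) -> ConcordanceFit:
    """OLS of protein fold change on transcript fold change.

    On the default log2 scale, nonpositive or undefined fold changes are
    dropped; ``scale='linear'`` regresses the values as passed.
    """
    x = np.asarray(fc_t, dtype=float)
    y = np.asarray(fc_p, dtype=float)
    if scale == "log2":
        keep = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
        x, y = np.log2(x[keep]), np.log2(y[keep])
    elif scale == "linear":
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if x.size < 3:
        raise ValueError("concordance regression needs at least 3 defined fold-change pairs")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in transcript fold changes")
    fit = stats.linregress(x, y)
    return ConcordanceFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=int(x.size),
        scale=scale,
    )


def marker_timeseries(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    catalog: Sequence[MemberGenome],
    genome_id: str,
    markers: Sequence[str],
    confidence: float = 0.95,
) -> dict:
    """Replicate mean ± CI per day for each requested marker of one genome.

    ``expr`` is a gene × sample table (RPKM or within-species protein
    percentages). Markers with several genes (e.g. duplicated yjbB) are summed
    across genes before summarization. Returns {marker: DataFrame(day, n,
    mean, ci_low, ci_high, log2_mean)}.
    """
    genome = next((g for g in catalog if g.genome_id == genome_id), None)
    if genome is None:
        raise KeyError(f"unknown genome {genome_id!r}")
    available = sorted({label for g in genome.genes for label in g.marker_labels})
    groups = day_replicate_groups(samples)
    out = {}
    for marker in markers:
        gene_ids = [g.gene_id for g in genome.genes if marker in g.marker_labels]
        if not gene_ids:
            raise KeyError(
                f"marker {marker!r} not annotated in genome {genome_id}; available: {available}"
            )
        series = expr.loc[[g for g in gene_ids if g in expr.index]].sum(axis=0)
        rows = []
        for day, cols in groups.items():
            summ = replicate_summary(series[cols], confidence=confidence)
            rows.append(
                {"day": day, "n": summ.n, "mean": summ.mean,
                 "ci_low": summ.ci_low, "ci_high": summ.ci_high,
                 "log2_mean": math.log2(summ.mean) if summ.mean > 0 else np.nan}
            )
        out[marker] = pd.DataFrame(rows)
    return out


def aggregate_subsystem(
    expr: pd.DataFrame, gene_ids: Sequence[str], catalog: Optional[Sequence[MemberGenome]] = None
) -> pd.Series:
    """Per-sample sum of expression over a subsystem's gene set (single genome).

    The sum is taken before any replicate summarization so that downstream CIs
    describe the subsystem total, matching how multi-protein complexes
    (photosystems, phycobiliproteins) are reported.
    """
    if not len(gene_ids):
        raise ValueError("empty subsystem gene set")
    missing = [g for g in gene_ids if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from expression table: {missing}")
    if catalog is not None:
        from .genome_catalog import gene_index

        idx = gene_index(catalog)
        genomes = {idx[g].genome_id for g in gene_ids if g in idx}
        if len(genomes) > 1:
            raise ValueError(f"subsystem spans multiple genomes: {sorted(genomes)}")
    return expr.loc[list(gene_ids)].sum(axis=0)


# ---------------------------------------------------------------------------
# Limitation signatures
# ---------------------------------------------------------------------------

def _marker_day_means(expr, samples, genome, marker):
    """Replicate-mean per day of the summed expression of a marker's genes."""
    gene_ids = [g.gene_id for g in genome.genes if marker in g.marker_labels]
    gene_ids = [g for g in gene_ids if g in expr.index]
    if not gene_ids:
        return None
    series = expr.loc[gene_ids].sum(axis=0)
    groups = day_replicate_groups(samples)
    return pd.Series({day: series[cols].mean() for day, cols in groups.items()})


def limitation_signatures(
    rpkm: RPKMMatrix,
    capabilities: CapabilityMatrix,
    catalog: Sequence[MemberGenome],
    p_threshold: float = 1.0,
    r_threshold: float = 0.8,
    expression_floor: float = 1.0,
    range_floor: float = 0.5,
) -> pd.DataFrame:
    """Phosphate-starvation scores and nitrogen-coupling classes per genome.

    P_score is log2 of the ratio of replicate-mean expression of the species'
    highest-affinity phosphate transporter between the last and first sampled
    days; ``P_limited`` calls scores >= ``p_threshold`` (default 1, i.e.
    2-fold — conservative relative to the ~4-fold signals that motivate it).

    N-coupling compares the log2 replicate-mean day series of amt and glnA:
    ``low_expression`` when either gene's mean expression is below
    ``expression_floor``; ``coupled`` when both series vary (log2 range >=
    ``range_floor``) and their Pearson correlation is >= ``r_threshold``;
    ``decoupled`` otherwise — including the flat-series case, since a
    correlation against a non-varying series is not evidence of co-regulation.
    """
    expr = rpkm.values
    samples = rpkm.samples
    days = sorted(samples["day"].unique())
    if len(days) < 2:
        raise ValueError("limitation signatures need at least two sampled days")

    rows = []
    for genome in sorted(catalog, key=lambda g: g.genome_id):
        gid = genome.genome_id
        # --- phosphate
        p_marker, p_score, p_limited = None, np.nan, None
        for fam in P_TRANSPORTER_HIERARCHY:
            means = _marker_day_means(expr, samples, genome, fam)
            if means is not None:
                p_marker = fam
                first, last = means[days[0]], means[days[-1]]
                if first > 0 and last > 0:
                    p_score = math.log2(last / first)
                    p_limited = p_score >= p_threshold
                break
        # --- nitrogen
        amt = _marker_day_means(expr, samples, genome, "amt")
        glnA = _marker_day_means(expr, samples, genome, "glnA")
        n_class, n_corr = "low_expression", np.nan
        if amt is not None and glnA is not None:
            if amt.mean() >= expression_floor and glnA.mean() >= expression_floor:
                la = np.log2(amt.where(amt > 0))
                lg = np.log2(glnA.where(glnA > 0))
                if la.isna().any() or lg.isna().any():
                    n_class = "decoupled"
                elif (la.max() - la.min() < range_floor) or (lg.max() - lg.min() < range_floor):
                    n_class = "decoupled"  # a flat series cannot evidence co-expression
                else:
                    n_corr = float(stats.pearsonr(la.values, lg.values)[0])
                    n_class = "coupled" if n_corr >= r_threshold else "decoupled"
        rows.append(
            {"genome_id": gid, "p_transporter": p_marker, "p_score": p_score,
             "p_limited": p_limited, "n_coupling": n_class, "n_correlation": n_corr}
        )
    return pd.DataFrame(rows).set_index("genome_id")
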