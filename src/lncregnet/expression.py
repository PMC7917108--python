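"""Detection, differential expression, and correlation over the FPKM matrix.

The DE caller here is a deliberately simple stand-in for assembly-level DE
tools (Ballgown and kin): a two-sample t-test on log2(FPKM+1) per feature
with Benjamini–Hochberg adjustment across features within a comparison.
Pipelines that have proper DE output can supply it as a precomputed TSV and
skip this caller entirely.

Pearson correlations can be computed on the 5 stage means (the default —
treatment stages are the experimental unit) or on all replicate columns;
the choice changes n and hence the p-value, so it is always explicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

__all__ = [
    "DERecord",
    "CorrelationResult",
    "detect_expressed",
    "pcc",
    "bh_adjust",
    "de_call",
    "de_call_all",
    "de_features",
    "stage_specific",
    "read_de_tsv",
    "write_de_tsv",
]


@dataclass(frozen=True)
class DERecord:
    feature_id: str
    comparison: str
    log2fc: float
    p_value: float
    q_value: float
    direction: str

    def __post_init__(self) -> None:
        for v in (self.p_value, self.q_value):
            if not (0.0 <= v <= 1.0):
                raise ValueError("p/q outside [0, 1]")
        if self.direction not in ("up", "down"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| > 1")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p outside [0, 1]")
        if self.n < 3:
            raise ValueError("n < 3")


def detect_expressed(
    expr: ExpressionMatrix, stage: str, min_fpkm: float = 0.1
) -> set[str]:
    """Features whose mean FPKM across the stage's replicates exceeds
    ``min_fpkm`` (strict >)."""
    samples = expr.stage_samples(stage)  # raises KeyError for unknown stage
    means = expr.values[samples].mean(axis=1)
    return set(means.index[means > min_fpkm])


def pcc(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with the two-sided p-value from
    the t-transform t = r*sqrt((n-2)/(1-r^2)) on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xm, ym = x - x.mean(), y - y.mean()
    r = float(np.dot(xm, ym) / np.sqrt(np.dot(xm, xm) * np.dot(ym, ym)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p_value=p, n=n)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def de_call(
    expr: ExpressionMatrix,
    stage_a: str,
    stage_b: str,
    alpha_q: float = 0.05,
) -> list[DERecord]:
    """Two-group t-test stand-in: log2(FPKM+1), equal-variance t, BH across
    features.  Returns records for ALL testable features; DE means
    ``q_value < alpha_q`` (filter with :func:`de_features`).

    Features with identical values in both groups are untestable and are
    assigned p = 1 (never DE).
    """
    sa = expr.stage_samples(stage_a)
    sb = expr.stage_samples(stage_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need >= 2 replicates per stage")
    la = np.log2(expr.values[sa].to_numpy() + 1.0)
    lb = np.log2(expr.values[sb].to_numpy() + 1.0)
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # identical-value features trigger a scipy precision warning; they are
        # handled explicitly below (p set to 1, never DE)
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(lb, la, axis=1, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)
    log2fc = lb.mean(axis=1) - la.mean(axis=1)
    q = bh_adjust(p)
    comparison = f"{stage_b}_vs_{stage_a}"
    return [
        DERecord(
            feature_id=fid,
            comparison=comparison,
            log2fc=float(fc),
            p_value=float(pv),
            q_value=float(qv),
            direction="up" if fc >= 0 else "down",
        )
        for fid, fc, pv, qv in zip(expr.feature_ids, log2fc, p, q)
    ]


def de_call_all(
    expr: ExpressionMatrix,
    control: str | None = None,
    alpha_q: float = 0.05,
) -> dict[str, list[DERecord]]:
    """DE records for every treatment stage vs the control stage (first of
    ``stage_order`` by default), keyed by comparison name."""
    control = control or expr.stage_order[0]
    out = {}
    for stage in expr.stage_order:
        if stage == control:
            continue
        recs = de_call(expr, control, stage, alpha_q=alpha_q)
        out[f"{stage}_vs_{control}"] = recs
    return out


def de_features(records: Iterable[DERecord], alpha_q: float = 0.05) -> set[str]:
    """Feature ids significant at ``q < alpha_q`` (strict)."""
    return {r.feature_id for r in records if r.q_value < alpha_q}


def stage_specific(
    detection_sets: Mapping[str, set[str]],
) -> dict[str, set[str]]:
    """Features detected in exactly one stage, keyed by that stage."""
    counts: dict[str, int] = {}
    for feats in detection_sets.values():
        for f in feats:
            counts[f] = counts.get(f, 0) + 1
    return {
        stage: {f for f in feats if counts[f] == 1}
        for stage, feats in detection_sets.items()
    }


DE_TSV_COLUMNS = ["feature_id", "comparison", "log2fc", "p_value", "q_value", "direction"]


def write_de_tsv(records: Iterable[DERecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records], columns=DE_TSV_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_de_tsv(path) -> list[DERecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        DERecord(
            feature_id=str(r.feature_id),
            comparison=str(r.comparison),
            log2fc=float(r.log2fc),
            p_value=float(r.p_value),
            q_value=float(r.q_value),
            direction=str(r.direction),
        )
        for r in df.itertuples(index=False)
    ]
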