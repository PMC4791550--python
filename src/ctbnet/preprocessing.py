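"""Expression preprocessing: normalization, probe filtering, differential
expression, gene selection and three-state discretization.

The pipeline turns a raw case/control time-course expression matrix into
the discrete gene-state matrix the CTBN learner consumes:

1. log2 transform + between-array normalization;
2. discard probes that are not reliably detected or have SD < 0.15
   over all samples;
3. per-time-point case-vs-control differential expression (Welch
   t-test, Benjamini-Hochberg FDR within each time point);
4. keep genes differentially expressed (q < 0.05) with |log2 FC| > 1
   at the same time point;
5. discretize fold changes into 3 bins: state 0 iff FC <= -1, state 1
   iff -1 < FC < 1, state 2 iff FC >= 1;
6. discard genes whose bin is constant across all time points and
   replicates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError

__all__ = [
    "ExpressionBundle",
    "SelectionConfig",
    "DiscreteStateMatrix",
    "normalize",
    "filter_probes",
    "fold_change",
    "differential_expression",
    "select_genes",
    "discretize",
    "drop_constant",
    "preprocess",
]

log = logging.getLogger(__name__)


@dataclass
class ExpressionBundle:
    """Expression matrix plus sample metadata (and optional detection p).

    ``values`` is probes x samples; ``samples`` is indexed by sample id
    with columns ``condition`` (case/control), ``time_h``, ``replicate``.
    ``log2`` flags whether values are already on the log2 scale.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    log2: bool = True

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise DataError(f"samples table missing metadata for columns: {sorted(missing)[:5]}")
        req = {"condition", "time_h", "replicate"}
        if not req.issubset(self.samples.columns):
            raise DataError(f"samples table must have columns {sorted(req)}")
        bad = set(self.samples["condition"]) - {"case", "control"}
        if bad:
            raise DataError(f"unknown condition labels: {sorted(bad)}")
        meta = self.samples.loc[list(self.values.columns)]
        dup = meta.duplicated(["condition", "time_h", "replicate"])
        if dup.any():
            raise DataError("duplicate (condition, time, replicate) cells in metadata")
        case_t = set(meta.loc[meta.condition == "case", "time_h"])
        ctrl_t = set(meta.loc[meta.condition == "control", "time_h"])
        if case_t != ctrl_t:
            raise DataError("case and control must share the time grid")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise DataError("detection_p must have the same shape as values")

    @property
    def times(self) -> list[float]:
        return sorted(set(self.samples.loc[list(self.values.columns), "time_h"]))

    def condition_columns(self, condition: str, time_h: float | None = None) -> list[str]:
        meta = self.samples.loc[list(self.values.columns)]
        mask = meta.condition == condition
        if time_h is not None:
            mask &= meta.time_h == time_h
        sub = meta[mask].sort_values(["time_h", "replicate"])
        return list(sub.index)

    def subset(self, probes) -> "ExpressionBundle":
        det = self.detection_p.loc[probes] if self.detection_p is not None else None
        return ExpressionBundle(self.values.loc[probes], self.samples, det, self.log2)


@dataclass
class SelectionConfig:
    """Filtering/selection thresholds (defaults follow the study settings)."""

    detection_p_max: float = 0.05
    detection_fraction: float = 0.5  # fraction of samples required detected
    literal_detection_filter: bool = False  # discard detected probes (literal reading)
    sd_min: float = 0.15
    de_alpha: float = 0.05  # FDR-adjusted
    fc_abs_min: float = 1.0  # log2
    bin_edges: tuple[float, float] = (-1.0, 1.0)
    bh_scope: str = "per_time"  # or "global"

    def __post_init__(self):
        errs = []
        if not 0 < self.detection_p_max < 1:
            errs.append("detection_p_max must be in (0, 1)")
        if not 0 < self.detection_fraction <= 1:
            errs.append("detection_fraction must be in (0, 1]")
        if self.sd_min < 0:
            errs.append("sd_min must be >= 0")
        if not 0 < self.de_alpha < 1:
            errs.append("de_alpha must be in (0, 1)")
        if self.fc_abs_min <= 0:
            errs.append("fc_abs_min must be > 0")
        if len(self.bin_edges) != 2 or self.bin_edges[0] >= self.bin_edges[1]:
            errs.append("bin_edges must be strictly increasing")
        if self.bh_scope not in ("per_time", "global"):
            errs.append("bh_scope must be 'per_time' or 'global'")
        if errs:
            raise ConfigError(errs)


@dataclass
class DiscreteStateMatrix:
    """Gene x (time, replicate) integer states in {0, 1, 2}."""

    states: pd.DataFrame  # MultiIndex columns (time_h, replicate)
    times: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not self.times:
            self.times = sorted(set(self.states.columns.get_level_values(0)))
        vals = self.states.to_numpy()
        if not np.isin(vals, [0, 1, 2]).all():
            raise DataError("states must be in {0, 1, 2}")

    @property
    def genes(self) -> list[str]:
        return list(self.states.index)

    @property
    def replicates(self) -> list[int]:
        return sorted(set(self.states.columns.get_level_values(1)))

    def replicate_matrix(self, r: int) -> pd.DataFrame:
        """Genes x times state matrix for one replicate."""
        sub = self.states.xs(r, axis=1, level=1)
        return sub[self.times]


def _quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Between-array quantile normalization: replace each column's sorted
    values by the mean sorted profile across columns."""
    order = np.argsort(values, axis=0)
    ranks = np.empty_like(order)
    rows = np.arange(values.shape[0])
    for j in range(values.shape[1]):
        ranks[order[:, j], j] = rows
    mean_profile = np.sort(values, axis=0).mean(axis=1)
    return mean_profile[ranks]


def normalize(bundle: ExpressionBundle, method: str = "quantile") -> ExpressionBundle:
    """log2 transform (if needed) and between-array normalization.

    ``method`` is one of ``quantile``, ``median`` (median-centering to
    the global median), or ``none``.  Idempotent on already-log2 input
    when method is ``none``.
    """
    if method not in ("quantile", "median", "none"):
        raise ConfigError(f"unknown normalization method: {method}")
    vals = bundle.values.to_numpy(dtype=float)
    if not bundle.log2:
        bad = np.where((vals <= 0).any(axis=1))[0]
        if bad.size:
            names = [bundle.values.index[i] for i in bad[:5]]
            raise DataError(f"non-positive linear intensities for probes: {names}")
        vals = np.log2(vals)
    if method == "quantile":
        vals = _quantile_normalize(vals)
    elif method == "median":
        med = np.median(vals, axis=0)
        vals = vals - med + med.mean()
    return ExpressionBundle(
        pd.DataFrame(vals, index=bundle.values.index, columns=bundle.values.columns),
        bundle.samples,
        bundle.detection_p,
        log2=True,
    )


def filter_probes(
    bundle: ExpressionBundle, config: SelectionConfig
) -> tuple[ExpressionBundle, dict[str, int]]:
    """Drop undetected and low-variance probes.

    A probe is kept when it is detected (detection p < ``detection_p_max``)
    in at least ``detection_fraction`` of samples and its SD over all
    samples is >= ``sd_min`` (SD < 0.15 probes are discarded; exactly
    0.15 is retained).  Returns the filtered bundle and removal counts.
    """
    n0 = len(bundle.values)
    keep = pd.Series(True, index=bundle.values.index)
    report = {"input": n0}
    if bundle.detection_p is not None:
        frac = (bundle.detection_p < config.detection_p_max).mean(axis=1)
        detected = frac >= config.detection_fraction
        keep &= ~detected if config.literal_detection_filter else detected
        report["removed_detection"] = int((~keep).sum())
    else:
        report["removed_detection"] = 0
    sd = bundle.values.std(axis=1, ddof=1)
    sd_ok = sd >= config.sd_min
    report["removed_sd"] = int((keep & ~sd_ok).sum())
    keep &= sd_ok
    report["retained"] = int(keep.sum())
    if report["retained"] == 0:
        raise DataError("all probes removed by filtering")
    log.info("filter_probes: %s", report)
    return bundle.subset(bundle.values.index[keep]), report


def fold_change(bundle: ExpressionBundle) -> pd.DataFrame:
    """log2 fold change per (gene, time, replicate).

    FC(g, t, r) = case(g, t, r) - mean over control replicates of
    control(g, t).  Returns genes x MultiIndex (time_h, replicate).
    """
    if not bundle.log2:
        raise DataError("fold_change requires log2-scale values")
    out = {}
    meta = bundle.samples.loc[list(bundle.values.columns)]
    for t in bundle.times:
        ctrl_cols = bundle.condition_columns("control", t)
        case_cols = bundle.condition_columns("case", t)
        if not ctrl_cols:
            raise DataError(f"missing control samples at time {t}")
        if not case_cols:
            raise DataError(f"missing case samples at time {t}")
        ctrl_mean = bundle.values[ctrl_cols].mean(axis=1)
        for c in case_cols:
            r = int(meta.loc[c, "replicate"])
            out[(t, r)] = bundle.values[c] - ctrl_mean
    fc = pd.DataFrame(out)
    fc.columns = pd.MultiIndex.from_tuples(fc.columns, names=["time_h", "replicate"])
    return fc


def differential_expression(
    bundle: ExpressionBundle, config: SelectionConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene, per-time Welch t-test (case vs control) with BH correction.

    Returns (p, q) DataFrames, genes x times.  The BH adjustment is
    applied within each time point by default (``bh_scope='global'``
    pools all tests).  Degenerate zero-variance groups: p = 1 when the
    group means are equal, p = 0 when they differ (the data leave no
    doubt either way).
    """
    config = config or SelectionConfig()
    pvals = {}
    for t in bundle.times:
        case = bundle.values[bundle.condition_columns("case", t)].to_numpy()
        ctrl = bundle.values[bundle.condition_columns("control", t)].to_numpy()
        if case.shape[1] < 2 or ctrl.shape[1] < 2:
            raise DataError(f"need >= 2 replicates per condition at time {t}")
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # zero-variance groups trigger a precision-loss warning; those
            # cells are overwritten by the explicit conventions below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
            p = np.asarray(res.pvalue, dtype=float)
        zero_var = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
        same_mean = np.isclose(case.mean(axis=1), ctrl.mean(axis=1))
        p = np.where(zero_var & same_mean, 1.0, p)
        p = np.where(zero_var & ~same_mean, 0.0, p)
        p = np.where(np.isnan(p), 1.0, p)
        pvals[t] = p
    pdf = pd.DataFrame(pvals, index=bundle.values.index)
    if config.bh_scope == "global":
        flat = pdf.to_numpy().ravel()
        q = multipletests(flat, method="fdr_bh")[1].reshape(pdf.shape)
        qdf = pd.DataFrame(q, index=pdf.index, columns=pdf.columns)
    else:
        qdf = pdf.apply(lambda col: multipletests(col, method="fdr_bh")[1], axis=0)
    return pdf, qdf


def select_genes(
    fc: pd.DataFrame, qvalues: pd.DataFrame, config: SelectionConfig | None = None
) -> list[str]:
    """Genes with q < de_alpha AND |mean-replicate FC| > fc_abs_min
    co-occurring at some time point."""
    config = config or SelectionConfig()
    if not fc.index.equals(qvalues.index):
        raise DataError("fold-change and q-value tables have different gene indices")
    mean_fc = fc.T.groupby(level="time_h").mean().T  # genes x times
    mean_fc = mean_fc[qvalues.columns]
    hit = (qvalues < config.de_alpha) & (mean_fc.abs() > config.fc_abs_min)
    selected = list(fc.index[hit.any(axis=1)])
    if not selected:
        log.warning("select_genes: empty selection")
    return selected


def discretize(
    fc: pd.DataFrame, bin_edges: tuple[float, float] = (-1.0, 1.0)
) -> DiscreteStateMatrix:
    """Discretize fold changes into 3 bins.

    State 0 iff FC <= lower edge; state 2 iff FC >= upper edge; state 1
    otherwise.  With the default edges, FC = -1 maps to state 0 and
    FC = +1 to state 2 (closed outer bins).
    """
    lo, hi = bin_edges
    if lo >= hi:
        raise ConfigError("bin_edges must be strictly increasing")
    vals = fc.to_numpy(dtype=float)
    if np.isnan(vals).any():
        g, t = np.argwhere(np.isnan(vals))[0]
        raise DataError(f"NaN fold change for gene {fc.index[g]} at column {fc.columns[t]}")
    states = np.ones(vals.shape, dtype=np.int64)
    states[vals <= lo] = 0
    states[vals >= hi] = 2
    return DiscreteStateMatrix(pd.DataFrame(states, index=fc.index, columns=fc.columns))


def drop_constant(matrix: DiscreteStateMatrix) -> tuple[DiscreteStateMatrix, list[str]]:
    """Remove genes whose state never changes across all time points and
    replicates; returns the reduced matrix and the removed gene ids."""
    vals = matrix.states.to_numpy()
    constant = (vals == vals[:, [0]]).all(axis=1)
    removed = list(matrix.states.index[constant])
    if constant.all():
        raise DataError("all genes constant after discretization")
    if removed:
        log.info("drop_constant: removed %d constant genes", len(removed))
    return DiscreteStateMatrix(matrix.states.loc[~constant]), removed


def preprocess(
    bundle: ExpressionBundle,
    config: SelectionConfig | None = None,
    normalize_method: str = "none",
) -> dict:
    """Full preprocessing chain; returns intermediates and the final
    discrete state matrix under keys ``normalized``, ``filtered``,
    ``filter_report``, ``fc``, ``p``, ``q``, ``selected``, ``states``,
    ``dropped_constant``."""
    config = config or SelectionConfig()
    normed = normalize(bundle, method=normalize_method)
    filtered, report = filter_probes(normed, config)
    fc = fold_change(filtered)
    p, q = differential_expression(filtered, config)
    selected = select_genes(fc, q, config)
    if not selected:
        raise DataError("no genes passed selection")
    states = discretize(fc.loc[selected], config.bin_edges)
    states, dropped = drop_constant(states)
    return {
        "normalized": normed,
        "filtered": filtered,
        "filter_report": report,
        "fc": fc,
        "p": p,
        "q": q,
        "selected": selected,
        "states": states,
        "dropped_constant": dropped,
    }
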