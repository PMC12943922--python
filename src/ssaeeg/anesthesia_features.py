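"""From per-epoch Hilbert features to aligned tables, phase summaries and BIS models.

The pipeline output for one recording is a time-indexed table of 12
parameters — CF1..CF6 (Hz) and TP1..TP6 (dB) — one per IMF, optionally with
an aligned BIS column.  Tables are aggregated onto a coarse grid (8 s by
default), combined across a cohort by cellwise medians, summarized per
anesthetic phase (maintenance / transition / emergence), and regressed
against BIS with ordinary least squares.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import (
    DegenerateInputError,
    EmptyInputError,
    EmptyModelError,
    MulticollinearityError,
    SchemaError,
)
from .hilbert_spectral import analyze_imf, imf_features
from .io_eeg import FEATURE_COLUMNS, EEGRecording, EpochingConfig, segment_epochs
from .ssa_core import DEFAULT_WINDOW_SAMPLES, Grouping, ssa_decompose_epoch

__all__ = [
    "RegressionModel",
    "PhaseSummary",
    "PHASES",
    "epoch_features",
    "align_to_grid",
    "cohort_median",
    "fit_mlr",
    "select_significant",
    "predict_bis",
    "phase_summary",
]

logger = logging.getLogger(__name__)

PHASES = ("maintenance", "transition", "emergence")
DEFAULT_GRID_SECONDS = 8.0
DEFAULT_SPAN_SECONDS = 600.0


@dataclasses.dataclass
class RegressionModel:
    """OLS fit of BIS on IMF parameters, with in-sample fit metrics."""

    intercept: float
    coefficients: dict[str, float]
    p_values: dict[str, float]
    r2: float
    mae: float
    rmse: float
    n_obs: int
    included_params: list[str]
    std_errors: dict[str, float] = dataclasses.field(default_factory=dict)

    def conf_int(self, param: str, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for one coefficient."""
        from scipy import stats as _st

        df = self.n_obs - len(self.included_params) - 1
        half = _st.t.ppf(0.5 + level / 2.0, df) * self.std_errors[param]
        c = self.coefficients[param]
        return (c - half, c + half)

    def coefficient_table(self) -> pd.DataFrame:
        """Tidy (param, coefficient, p_value) table, intercept first."""
        rows = [{"param": "intercept", "coefficient": self.intercept, "p_value": np.nan}]
        rows += [
            {"param": p, "coefficient": self.coefficients[p], "p_value": self.p_values[p]}
            for p in self.included_params
        ]
        return pd.DataFrame(rows)


@dataclasses.dataclass
class PhaseSummary:
    """Per-parameter medians/IQRs per phase with nonparametric tests.

    ``stats`` is indexed by (parameter, phase) with columns
    median / iqr / pct_change (relative to the maintenance median);
    ``tests`` is indexed by parameter with the Kruskal-Wallis omnibus
    p-value and Bonferroni-corrected pairwise Mann-Whitney p-values.
    Phases with fewer than three rows are flagged and get NaN p-values.
    """

    stats: pd.DataFrame
    tests: pd.DataFrame
    phase_bounds: dict[str, tuple[float, float]]


def epoch_features(
    rec: EEGRecording,
    cfg: EpochingConfig | None = None,
    grouping: Grouping | None = None,
    K: int = DEFAULT_WINDOW_SAMPLES,
    trim_seconds: float = 0.0,
    power_weighted: bool = True,
) -> pd.DataFrame:
    """Per-epoch feature table: one row per epoch center with CF1-6, TP1-6.

    Silent IMFs (and fully degenerate epochs) yield missing cells rather
    than errors, so flat stretches of a recording do not abort the run.
    """
    cfg = cfg or EpochingConfig()
    grouping = grouping or Grouping()
    epochs = segment_epochs(rec, cfg)
    rows = np.full((len(epochs), len(FEATURE_COLUMNS)), np.nan)
    centers = np.empty(len(epochs))
    n_groups = grouping.n_groups
    for e, epoch in enumerate(epochs):
        centers[e] = epoch.t_center
        decomp = ssa_decompose_epoch(epoch, cfg, grouping, K=K)
        if decomp.degenerate:
            continue
        for g in range(n_groups):
            aimf = analyze_imf(decomp.imfs[g], rec.fs, trim_seconds=trim_seconds)
            feats = imf_features(aimf, power_weighted=power_weighted)
            rows[e, g] = feats.cf
            rows[e, n_groups + g] = feats.tp_db
    table = pd.DataFrame(rows, index=pd.Index(centers, name="t"), columns=FEATURE_COLUMNS)
    table.attrs["provenance"] = rec.recording_id or "recording"
    return table


def align_to_grid(
    features: pd.DataFrame,
    grid_seconds: float = DEFAULT_GRID_SECONDS,
    bis: pd.Series | None = None,
) -> pd.DataFrame:
    """Aggregate epoch-grid features onto a uniform coarse grid.

    Grid cell ``t`` covers ``[t, t + grid)`` and takes the median of the
    epochs whose centers fall inside; cells without epochs stay missing.
    A sparse BIS series is matched to each grid time at the nearest
    timestamp within half a cell.
    """
    if len(features) == 0:
        raise EmptyInputError("no epoch features to align")
    t = np.asarray(features.index, dtype=float)
    n_cells = int(np.floor(t.max() / grid_seconds)) + 1
    grid = np.arange(n_cells) * grid_seconds
    cell = np.floor(t / grid_seconds).astype(int)
    agg = features.groupby(cell).median()
    out = agg.reindex(np.arange(n_cells))
    out.index = pd.Index(grid, name="t")
    if bis is not None and len(bis):
        bt = np.asarray(bis.index, dtype=float)
        bv = bis.to_numpy(dtype=float)
        matched = np.full(n_cells, np.nan)
        pos = np.searchsorted(bt, grid)
        for i, g in enumerate(grid):
            candidates = [j for j in (pos[i] - 1, pos[i]) if 0 <= j < bt.size]
            if not candidates:
                continue
            j = min(candidates, key=lambda j: abs(bt[j] - g))
            if abs(bt[j] - g) <= grid_seconds / 2.0:
                matched[i] = bv[j]
        out["BIS"] = matched
    out.attrs["provenance"] = features.attrs.get("provenance", "recording")
    return out


def cohort_median(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Cellwise median across recordings sharing a grid (missing cells ignored)."""
    if not tables:
        raise EmptyInputError("no feature tables supplied")
    index = tables[0].index
    for t in tables[1:]:
        if len(t.index) != len(index) or not np.allclose(t.index, index):
            raise SchemaError("feature tables do not share a common grid")
    stacked = pd.concat(tables, keys=range(len(tables)))
    out = stacked.groupby(level=1).median()
    out.index.name = "t"
    out.attrs["provenance"] = "cohort-median"
    return out


def _complete_cases(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"table lacks required columns: {missing}")
    sub = table[columns]
    kept = sub.dropna()
    dropped = len(sub) - len(kept)
    if dropped:
        logger.info("dropping %d/%d incomplete rows from fit", dropped, len(sub))
    return kept


def _check_design(X: pd.DataFrame) -> None:
    const = [c for c in X.columns if np.nanstd(X[c].to_numpy()) == 0]
    if const:
        raise MulticollinearityError(const, f"constant feature columns: {const}")
    design = np.column_stack([np.ones(len(X)), X.to_numpy()])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # pivoted QR localizes the dependent columns
        from scipy.linalg import qr

        _, R, piv = qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        bad = [piv[i] for i in range(len(diag)) if diag[i] <= tol]
        names = ["intercept" if j == 0 else X.columns[j - 1] for j in sorted(bad)]
        raise MulticollinearityError(names)


def fit_mlr(
    table: pd.DataFrame,
    params: list[str] | None = None,
    target: str = "BIS",
) -> RegressionModel:
    """Ordinary least squares of the target on the chosen parameters.

    Complete-case: rows with any missing required cell are dropped (and
    counted in the log).  Reports per-coefficient two-sided t-test p-values
    and in-sample R², MAE and RMSE.
    """
    params = list(params) if params is not None else [c for c in FEATURE_COLUMNS if c in table.columns]
    data = _complete_cases(table, params + [target])
    if len(data) < len(params) + 2:
        raise EmptyInputError(
            f"need at least {len(params) + 2} complete rows, have {len(data)}"
        )
    X = data[params]
    _check_design(X)
    y = data[target].to_numpy()
    res = sm.OLS(y, sm.add_constant(X.to_numpy())).fit()
    resid = y - res.fittedvalues
    return RegressionModel(
        intercept=float(res.params[0]),
        coefficients={p: float(res.params[i + 1]) for i, p in enumerate(params)},
        p_values={p: float(res.pvalues[i + 1]) for i, p in enumerate(params)},
        r2=float(res.rsquared),
        mae=float(np.mean(np.abs(resid))),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n_obs=int(res.nobs),
        included_params=params,
        std_errors={p: float(res.bse[i + 1]) for i, p in enumerate(params)},
    )


def select_significant(
    model: RegressionModel,
    table: pd.DataFrame,
    alpha: float = 0.05,
    target: str = "BIS",
) -> RegressionModel:
    """One-shot significance screening: keep p < alpha from the full fit, refit.

    No stepwise iteration — the reduced model is fit exactly once on the
    surviving parameters.
    """
    keep = [p for p in model.included_params if model.p_values[p] < alpha]
    if not keep:
        raise EmptyModelError(f"no parameters significant at alpha={alpha}")
    if keep == model.included_params:
        return model
    return fit_mlr(table, params=keep, target=target)


def predict_bis(model: RegressionModel, table: pd.DataFrame) -> pd.Series:
    """Linear prediction per row; rows with missing inputs predict missing."""
    missing = [p for p in model.included_params if p not in table.columns]
    if missing:
        raise SchemaError(f"table lacks model parameters: {missing}")
    pred = np.full(len(table), model.intercept, dtype=float)
    for p in model.included_params:
        pred = pred + model.coefficients[p] * table[p].to_numpy(dtype=float)
    return pd.Series(pred, index=table.index, name="predicted_BIS")


def phase_summary(
    table: pd.DataFrame,
    span_seconds: float = DEFAULT_SPAN_SECONDS,
    params: list[str] | None = None,
) -> PhaseSummary:
    """Split the span into three equal phases and summarize each parameter.

    For a 600-s span the phases are three 200-s periods (maintenance,
    transition, emergence).  Per parameter: phase median, IQR, and %change
    = 100·(median_phase − median_maint)/|median_maint|; omnibus
    Kruskal-Wallis across the three phases and pairwise Mann-Whitney U with
    Bonferroni correction (×3).
    """
    params = params or [c for c in FEATURE_COLUMNS if c in table.columns]
    third = span_seconds / 3.0
    t = np.asarray(table.index, dtype=float)
    bounds = {
        PHASES[0]: (0.0, third),
        PHASES[1]: (third, 2 * third),
        PHASES[2]: (2 * third, span_seconds),
    }
    groups = {
        ph: table.loc[(t >= lo) & (t < hi + (1e-9 if ph == PHASES[-1] else 0.0))]
        for ph, (lo, hi) in bounds.items()
    }

    stat_rows = []
    test_rows = []
    pairs = [(PHASES[1], PHASES[0]), (PHASES[2], PHASES[0]), (PHASES[2], PHASES[1])]
    for param in params:
        samples = {ph: g[param].dropna().to_numpy() for ph, g in groups.items()}
        med_maint = np.median(samples[PHASES[0]]) if samples[PHASES[0]].size else np.nan
        for ph in PHASES:
            x = samples[ph]
            med = np.median(x) if x.size else np.nan
            iqr = (np.percentile(x, 75) - np.percentile(x, 25)) if x.size else np.nan
            if ph == PHASES[0]:
                pct = 0.0 if np.isfinite(med) else np.nan
            elif np.isfinite(med) and np.isfinite(med_maint) and med_maint != 0:
                pct = 100.0 * (med - med_maint) / abs(med_maint)
            else:
                pct = np.nan
            stat_rows.append(
                {"param": param, "phase": ph, "median": med, "iqr": iqr, "pct_change": pct}
            )
        enough = all(samples[ph].size >= 3 for ph in PHASES)
        row = {"param": param, "insufficient_data": not enough}
        if enough:
            try:
                row["kruskal_p"] = float(
                    sps.kruskal(*(samples[ph] for ph in PHASES)).pvalue
                )
            except ValueError:  # all values identical across phases
                row["kruskal_p"] = 1.0
            for a, b in pairs:
                try:
                    p = float(sps.mannwhitneyu(samples[a], samples[b]).pvalue)
                except ValueError:  # degenerate (e.g. identical constant) samples
                    p = 1.0
                row[f"p_{a}_vs_{b}"] = min(1.0, 3.0 * p)
        else:
            row["kruskal_p"] = np.nan
            for a, b in pairs:
                row[f"p_{a}_vs_{b}"] = np.nan
        test_rows.append(row)

    stats_df = pd.DataFrame(stat_rows).set_index(["param", "phase"])
    tests_df = pd.DataFrame(test_rows).set_index("param")
    return PhaseSummary(stats=stats_df, tests=tests_df, phase_bounds=bounds)
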