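"""Peak-table preprocessing: drift correction, filtering, scaling, screening.

QC-SVRC drift correction
------------------------
LC-MS intensities drift with injection order within an acquisition batch.
Pooled QC samples, injected at regular intervals, measure that drift: for
each (feature, batch) an epsilon-support-vector regression with an RBF kernel
is fitted to QC intensity versus injection order, and every sample's
intensity is rescaled by ``reference / trend(injection)`` where the
reference is the median QC intensity. The correction is multiplicative, so
zeros stay zero, missing cells stay missing, and signs never change.

SVR hyperparameters (per feature/batch, all overridable via ``svr_params``):

* ``epsilon`` — 5% of the feature's median QC intensity, matching typical
  pooled-QC technical repeatability (a wider tube caps the removable drift
  at the tube width; a narrower one chases replicate noise);
* ``C`` — chosen from ``{1, 10, 1e2, 1e3, 1e4} x median QC intensity`` by
  leave-one-out RMSE over the QC points;
* ``gamma`` — 1 / median pairwise squared injection-order distance among the
  batch's QCs (median heuristic; lengthscale of the drift trend).

Features with fewer than ``min_qc`` QC points in a batch, or whose fitted
trend is not strictly positive where applied, pass through unchanged and are
flagged in the report.

Also here: blank/missingness feature filtering, half-minimum imputation +
log10 + autoscaling (train-parameterised, leakage-safe), and the Welch t /
Benjamini-Hochberg univariate screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR
from statsmodels.stats.multitest import multipletests

from .cohort_io import PeakTable

CORRECTED = "corrected"
SKIPPED_QC = "skipped_insufficient_qc"
SKIPPED_DEGENERATE = "skipped_degenerate"

DEFAULT_SVR_PARAMS = {
    "epsilon_frac": 0.05,
    "c_grid": (1.0, 10.0, 100.0, 1000.0, 10000.0),  # x median QC intensity
}


@dataclass
class CorrectionFit:
    """Per (feature, batch) correction status and diagnostics."""

    report: pd.DataFrame  # index (feature, batch): status, n_qc, ref, C

    def status_counts(self) -> pd.Series:
        return self.report["status"].value_counts()


def _fit_qc_trend(orders: np.ndarray, values: np.ndarray,
                  params: dict) -> tuple[SVR | None, float]:
    """LOO-selected RBF SVR of QC intensity on injection order.

    Returns (fitted SVR or None if degenerate, selected C).
    """
    med = float(np.median(values))
    if med <= 0:
        return None, np.nan
    eps = params["epsilon_frac"] * med
    d2 = (orders[:, None] - orders[None, :]) ** 2
    med_d2 = float(np.median(d2[np.triu_indices_from(d2, k=1)]))
    gamma = 1.0 / med_d2 if med_d2 > 0 else "scale"
    Xq = orders.reshape(-1, 1).astype(float)
    best_c, best_rmse = None, np.inf
    n = len(values)
    for cf in params["c_grid"]:
        c = cf * med
        sq = 0.0
        for i in range(n):
            m = np.ones(n, dtype=bool)
            m[i] = False
            svr = SVR(kernel="rbf", C=c, epsilon=eps, gamma=gamma)
            svr.fit(Xq[m], values[m])
            sq += (svr.predict(Xq[~m])[0] - values[i]) ** 2
        rmse = np.sqrt(sq / n)
        if rmse < best_rmse - 1e-12:
            best_rmse, best_c = rmse, c
    svr = SVR(kernel="rbf", C=best_c, epsilon=eps, gamma=gamma)
    svr.fit(Xq, values)
    return svr, best_c


def qc_svrc_correct(peak_table: PeakTable, min_qc: int = 5,
                    svr_params: dict | None = None,
                    ) -> tuple[PeakTable, CorrectionFit]:
    """Within-batch QC-SVRC intensity-drift correction.

    Fits the QC trend per feature and batch and rescales *all* samples of
    that batch (study and QC alike) to the median QC level. Batches are
    processed independently, so processing order cannot matter.
    """
    params = {**DEFAULT_SVR_PARAMS, **(svr_params or {})}
    if not (peak_table.role == "qc").any():
        raise ValueError(
            "no QC samples: cannot drift-correct. Provide QC injections or "
            "mark the manifest `corrected: true`.")
    out = peak_table.intensities.copy()
    rows = []
    for b in sorted(peak_table.batch.unique()):
        in_batch = peak_table.batch == b
        qc_mask = in_batch & (peak_table.role == "qc")
        orders_all = peak_table.injection_order[in_batch].to_numpy(float)
        ids_all = peak_table.intensities.index[in_batch]
        qc_orders = peak_table.injection_order[qc_mask].to_numpy(float)
        for feat in peak_table.feature_ids:
            v = peak_table.intensities.loc[qc_mask, feat].to_numpy(float)
            ok = np.isfinite(v)
            row = {"feature": feat, "batch": b, "n_qc": int(ok.sum()),
                   "reference": np.nan, "C": np.nan}
            if ok.sum() < min_qc:
                rows.append({**row, "status": SKIPPED_QC})
                continue
            svr, c = _fit_qc_trend(qc_orders[ok], v[ok], params)
            if svr is None:
                rows.append({**row, "status": SKIPPED_DEGENERATE})
                continue
            trend = svr.predict(orders_all.reshape(-1, 1))
            raw = out.loc[ids_all, feat].to_numpy(float)
            applied = np.isfinite(raw)
            if np.any(trend[applied] <= 0):
                rows.append({**row, "status": SKIPPED_DEGENERATE})
                continue
            ref = float(np.median(v[ok]))
            corrected = raw.copy()
            corrected[applied] = raw[applied] * ref / trend[applied]
            out.loc[ids_all, feat] = corrected
            rows.append({**row, "status": CORRECTED, "reference": ref, "C": c})
    report = pd.DataFrame(rows).set_index(["feature", "batch"])
    pt = PeakTable(out, peak_table.batch.copy(),
                   peak_table.injection_order.copy(), peak_table.role.copy())
    return pt, CorrectionFit(report=report)


def qc_rsd(peak_table: PeakTable) -> pd.Series:
    """Per-feature relative standard deviation over QC samples (%)."""
    qc = peak_table.rows("qc")
    return 100.0 * qc.std(ddof=1) / qc.mean()


# ---------------------------------------------------------------------------
# feature filtering
# ---------------------------------------------------------------------------

def filter_features(peak_table: PeakTable, blank_ratio: float = 3.0,
                    max_missing: float = 0.5,
                    ) -> tuple[PeakTable, pd.DataFrame]:
    """Drop background and poorly-detected features.

    A feature is dropped when its mean study intensity is below
    ``blank_ratio`` times its mean blank intensity (background signal), or
    when it is missing in more than ``max_missing`` of study samples. With no
    blank rows the blank filter is skipped with a warning.
    """
    study = peak_table.rows("study")
    blanks = peak_table.rows("blank")
    study_mean = study.mean()
    missing_frac = study.isna().mean()
    drop_missing = missing_frac > max_missing
    if blanks.empty:
        warnings.warn("no blank samples: blank filter skipped", stacklevel=2)
        drop_blank = pd.Series(False, index=study.columns)
        blank_mean = pd.Series(np.nan, index=study.columns)
    else:
        blank_mean = blanks.mean().fillna(0.0)
        drop_blank = study_mean.fillna(0.0) < blank_ratio * blank_mean
    report = pd.DataFrame({
        "study_mean": study_mean, "blank_mean": blank_mean,
        "missing_frac": missing_frac, "dropped_blank": drop_blank,
        "dropped_missing": drop_missing,
        "kept": ~(drop_blank | drop_missing)})
    keep = report.index[report["kept"]]
    if len(keep) == 0:
        raise ValueError("all features dropped by filtering")
    pt = PeakTable(peak_table.intensities[keep], peak_table.batch.copy(),
                   peak_table.injection_order.copy(), peak_table.role.copy())
    return pt, report


# ---------------------------------------------------------------------------
# imputation + scaling
# ---------------------------------------------------------------------------

@dataclass
class Scaler:
    """Half-minimum imputation, log10, autoscale — train-parameterised.

    All parameters come from the training matrix only, so applying the
    scaler to held-out samples leaks nothing. Zero-variance (or all-missing)
    training features are excluded and recorded.
    """

    half_min: pd.Series = field(default_factory=pd.Series)
    mean: pd.Series = field(default_factory=pd.Series)
    sd: pd.Series = field(default_factory=pd.Series)
    features: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    def fit(self, train: pd.DataFrame) -> "Scaler":
        A = train.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cols
            floor = np.nanmin(A, axis=0)
        half_min = np.where(np.isfinite(floor) & (floor > 0),
                            floor / 2.0, 1e-12)
        filled = np.where(np.isfinite(A) & (A > 0), A, half_min[None, :])
        logged = np.log10(filled)
        mean = logged.mean(axis=0)
        sd = logged.std(axis=0, ddof=1)
        usable = (sd > 0) & np.isfinite(sd) & np.isfinite(mean)
        self.excluded = list(train.columns[~usable])
        if self.excluded:
            warnings.warn(
                f"{len(self.excluded)} zero-variance/all-missing features "
                "excluded from scaling", stacklevel=2)
        cols = train.columns[usable]
        self.features = list(cols)
        self.half_min = pd.Series(half_min[usable], index=cols)
        self.mean = pd.Series(mean[usable], index=cols)
        self.sd = pd.Series(sd[usable], index=cols)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        A = X[self.features].to_numpy(dtype=float)
        hm = self.half_min.to_numpy()
        filled = np.where(np.isfinite(A) & (A > 0), A, hm[None, :])
        Z = (np.log10(filled) - self.mean.to_numpy()) / self.sd.to_numpy()
        return pd.DataFrame(Z, index=X.index, columns=self.features)

    def inverse_transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        return 10.0 ** (Z[self.features] * self.sd + self.mean)


def impute_and_scale(train_matrix: pd.DataFrame,
                     apply_matrix: pd.DataFrame | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame | None, Scaler]:
    """Scale train and (optionally) apply matrices with train-derived state."""
    scaler = Scaler().fit(train_matrix)
    train_scaled = scaler.transform(train_matrix)
    applied = None if apply_matrix is None else scaler.transform(apply_matrix)
    return train_scaled, applied, scaler


# ---------------------------------------------------------------------------
# univariate screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    table: pd.DataFrame  # per feature: t, p, q, selected
    alpha: float

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def univariate_screen(scaled: pd.DataFrame, group_a, group_b,
                      alpha: float = 0.05) -> ScreenResult:
    """Welch two-sample t per feature with Benjamini-Hochberg adjustment.

    ``group_a``/``group_b`` are sample-id lists; selection is q < alpha.
    """
    a = scaled.loc[list(group_a)].to_numpy(float)
    b = scaled.loc[list(group_b)].to_numpy(float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    table = pd.DataFrame({"t": t, "p": p, "q": q, "selected": q < alpha},
                         index=scaled.columns)
    return ScreenResult(table=table, alpha=alpha)
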