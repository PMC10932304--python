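"""Partial least squares for two-class discriminant analysis (PLS1-DA).

NIPALS with X-deflation. For a single response the NIPALS component is
closed-form (no iteration): per component *a*,

    w_a = X'y / ||X'y||        (weights)
    t_a = X w_a                (scores)
    p_a = X't_a / (t_a't_a)    (X loadings)
    q_a = y't_a / (t_a't_a)    (y loading)
    X <- X - t_a p_a',  y <- y - q_a t_a

Regression coefficients b = W (P'W)^{-1} q map centred X to centred y, so
predictions are ``(X - x_mean) b + y_mean``. X is expected pre-scaled
(autoscaling lives in :mod:`dili_ternary.preprocess`); the fit still centres
defensively and records the means. y is centred, never scaled.

Class encoding is a map ``{target: hi, rest: lo}``; the decision threshold is
the midpoint. The default 0/1 encoding puts raw predicted values on the 0-1
axis scale the ternary representation reads as 0%-100%; the symmetric +1/-1
encoding is available and affinely equivalent for classification.

Variable importance in projection (VIP) for feature *j* over A components::

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ),   SSY_a = q_a^2 t_a't_a

with unit-norm w_a, so mean(VIP^2) = 1 exactly.

Serialization: :func:`model_to_dict` / :func:`model_from_dict` give a
versioned pure-JSON schema (``{"format": "dili-ternary-pls", "version": 1,
...}``; matrices as nested lists, row-major).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-12
SCHEMA = "dili-ternary-pls"
SCHEMA_VERSION = 1

ENCODINGS = {
    "01": {"hi": 1.0, "lo": 0.0},
    "pm1": {"hi": 1.0, "lo": -1.0},
}


class RankError(ValueError):
    """Requested more latent variables than the data support."""


@dataclass
class PLSModel:
    """A fitted PLS1 model (weights, loadings, scores, coefficients)."""

    n_lv: int
    x_weights: np.ndarray     # (p, A), unit-norm columns
    x_loadings: np.ndarray    # (p, A)
    x_scores: np.ndarray      # (n_train, A)
    y_loadings: np.ndarray    # (A,)
    coef: np.ndarray          # (p,) for centred data
    x_mean: np.ndarray        # (p,)
    y_mean: float
    class_encoding: dict[str, float] = field(default_factory=lambda: dict(ENCODINGS["01"]))
    feature_ids: list[str] | None = None

    @property
    def decision_threshold(self) -> float:
        return 0.5 * (self.class_encoding["hi"] + self.class_encoding["lo"])

    def coef_for(self, a: int) -> np.ndarray:
        """Regression coefficients using only the first ``a`` components.

        NIPALS components are nested, so one fit at A_max yields the whole
        complexity path — used by cross-validated LV selection.
        """
        if not 1 <= a <= self.n_lv:
            raise ValueError(f"a must be in 1..{self.n_lv}")
        W, P, q = self.x_weights[:, :a], self.x_loadings[:, :a], self.y_loadings[:a]
        return W @ np.linalg.solve(P.T @ W, q)


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int,
            encoding: str | dict[str, float] = "01",
            feature_ids: list[str] | None = None) -> PLSModel:
    """Fit a PLS1 model by NIPALS with X- and y-deflation.

    ``y`` may be given as encoded numeric values or is produced upstream by
    :func:`encode_labels`. Deterministic: the weight vector comes from the
    X'y direction, no random initialisation.

    Raises :class:`RankError` if ``n_lv`` exceeds the effective rank of X
    (deflation exhausts the covariance before n_lv components) and
    ``ValueError`` for constant y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) with len(y) == n")
    n, p = X.shape
    if np.ptp(y) == 0:
        raise ValueError("constant y: nothing to discriminate")
    if n_lv < 1 or n_lv > min(n - 1, p):
        raise RankError(f"n_lv={n_lv} outside 1..min(n-1, p)={min(n - 1, p)}")
    enc = dict(ENCODINGS[encoding]) if isinstance(encoding, str) else dict(encoding)

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean
    y_scale = float(np.linalg.norm(yd))

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    for a in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= _EPS * max(1.0, y_scale):
            raise RankError(
                f"covariance exhausted after {a} components; n_lv={n_lv} "
                "exceeds the effective rank")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _EPS:
            raise RankError(f"degenerate score vector at component {a + 1}")
        pa = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pa)
        yd = yd - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa

    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(n_lv=n_lv, x_weights=W, x_loadings=P, x_scores=T,
                    y_loadings=q, coef=coef, x_mean=x_mean, y_mean=y_mean,
                    class_encoding=enc, feature_ids=list(feature_ids) if feature_ids else None)


def predict(model: PLSModel, X_new: np.ndarray,
            n_components: int | None = None) -> np.ndarray:
    """Continuous predicted values for new (pre-scaled) samples.

    Values are unbounded; classification thresholds at
    ``model.decision_threshold``. ``n_components`` evaluates a truncated
    model along the NIPALS path.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.coef.shape[0]:
        raise ValueError(
            f"feature mismatch: model has {model.coef.shape[0]} features, "
            f"X_new has {X_new.shape[1]}")
    b = model.coef if n_components is None else model.coef_for(n_components)
    return (X_new - model.x_mean) @ b + model.y_mean


def encode_labels(labels, target: str,
                  encoding: str | dict[str, float] = "01") -> np.ndarray:
    """One-vs-rest encode string labels for a target class."""
    enc = ENCODINGS[encoding] if isinstance(encoding, str) else encoding
    return np.asarray([enc["hi"] if l == target else enc["lo"] for l in labels],
                      dtype=float)


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable importance in projection; mean of squared VIPs is 1."""
    ssy = model.y_loadings ** 2 * np.einsum("ia,ia->a", model.x_scores,
                                            model.x_scores)
    total = ssy.sum()
    if total <= _EPS:
        raise ValueError("zero explained y variance: VIP undefined")
    wnorm2 = model.x_weights ** 2  # columns already unit norm
    p = model.x_weights.shape[0]
    return np.sqrt(p * (wnorm2 @ ssy) / total)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: PLSModel) -> dict:
    return {
        "format": SCHEMA,
        "version": SCHEMA_VERSION,
        "n_lv": model.n_lv,
        "x_weights": model.x_weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "x_scores": model.x_scores.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "coef": model.coef.tolist(),
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "class_encoding": model.class_encoding,
        "feature_ids": model.feature_ids,
    }


def model_from_dict(data: dict) -> PLSModel:
    if data.get("format") != SCHEMA:
        raise ValueError(f"not a {SCHEMA} payload")
    if data.get("version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {data.get('version')}")
    return PLSModel(
        n_lv=int(data["n_lv"]),
        x_weights=np.asarray(data["x_weights"], dtype=float),
        x_loadings=np.asarray(data["x_loadings"], dtype=float),
        x_scores=np.asarray(data["x_scores"], dtype=float),
        y_loadings=np.asarray(data["y_loadings"], dtype=float),
        coef=np.asarray(data["coef"], dtype=float),
        x_mean=np.asarray(data["x_mean"], dtype=float),
        y_mean=float(data["y_mean"]),
        class_encoding={k: float(v) for k, v in data["class_encoding"].items()},
        feature_ids=data.get("feature_ids"),
    )
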