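"""One-vs-rest PLS-DA ensemble with subject-wise double cross-validation.

Three binary PLS-DA models separate each phenotype from the other two:
cholestatic vs (hepatocellular + recovered), hepatocellular vs (cholestatic +
recovered), recovered vs (cholestatic + hepatocellular). Mixed-type patients
never enter training; their samples are decomposed by the final ensemble.

Cross-validation is *subject-wise*: folds partition patients, and every
sample of a patient travels with its patient, so longitudinal replicates of
one subject can never straddle a train/test boundary. Double CV nests two
such loops: the outer loop holds patients out for an honest out-of-sample
error estimate; the inner loop, run entirely within the outer-training
patients, selects the number of latent variables (LVs) by classification CV
accuracy (one-standard-error rule by default) and the VIP >= 1 feature set.
All data-dependent state — imputation/scaling parameters, LV count, VIP
selection — is recomputed inside each training partition, so nothing leaks
from held-out samples.

Per training partition the model is built in two stages: stage 1 fits PLS on
all features with the selected LV count and scores features by VIP; stage 2
recomputes the scaler on the VIP >= threshold features and refits. Both
models are retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import plsda_core
from .plsda_core import PLSModel, RankError
from .preprocess import Scaler

CLASSES = ("cholestatic", "hepatocellular", "recovered")
DEFAULT_MAX_LV = 6


class FoldError(ValueError):
    """Fold construction or degeneracy problem."""


# ---------------------------------------------------------------------------
# subject-wise folds
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Patient-level fold assignments for nested CV."""

    outer_folds: list[list[str]]            # k_outer patient-id lists
    inner_folds: dict[int, list[list[str]]]  # per outer fold: k_inner lists
    k_outer: int
    k_inner: int
    seed: int
    excluded_patients: list[str] = field(default_factory=list)


def make_subject_folds(patient_ids, k: int, seed: int) -> list[list[str]]:
    """Deal shuffled patients round-robin into k folds (patients never split)."""
    patients = list(dict.fromkeys(patient_ids))  # unique, order-stable
    if k < 1 or k > len(patients):
        raise FoldError(f"k={k} incompatible with {len(patients)} patients")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, pid in enumerate(order):
        folds[i % k].append(pid)
    return folds


def build_fold_plan(patient_ids, k_outer: int, k_inner: int, seed: int,
                    exclude: set[str] | None = None) -> FoldPlan:
    """Nested subject-wise plan; excluded (mixed-type) patients enter no fold."""
    exclude = set(exclude or ())
    usable = [p for p in dict.fromkeys(patient_ids) if p not in exclude]
    outer = make_subject_folds(usable, k_outer, seed)
    inner: dict[int, list[list[str]]] = {}
    for i, fold in enumerate(outer):
        train_patients = [p for p in usable if p not in set(fold)]
        inner[i] = make_subject_folds(train_patients, k_inner, seed + i + 1)
    return FoldPlan(outer_folds=outer, inner_folds=inner, k_outer=k_outer,
                    k_inner=k_inner, seed=seed,
                    excluded_patients=sorted(exclude))


def mixed_type_patients(labels: pd.Series, patients: pd.Series) -> set[str]:
    """Patients with any sample labelled mixed (excluded from training)."""
    return set(patients[labels == "mixed"])


# ---------------------------------------------------------------------------
# LV selection
# ---------------------------------------------------------------------------

def _binary_accuracy(pred: np.ndarray, y: np.ndarray, threshold: float) -> float:
    return float(np.mean((pred >= threshold) == (y >= threshold)))


def select_n_lv(X: pd.DataFrame, y: pd.Series, patients: pd.Series,
                folds: list[list[str]], max_lv: int,
                one_se: bool = True) -> tuple[int, pd.DataFrame]:
    """Choose the LV count by subject-wise CV classification accuracy.

    For each fold, the scaler and a max_lv-component PLS are fitted on the
    training patients only and the whole complexity path is evaluated on the
    held-out patients. Returns the chosen count plus the accuracy curve
    (mean and standard error per LV). ``one_se=True`` picks the smallest
    count within one standard error of the maximum; otherwise the argmax
    (smallest on ties).
    """
    if max_lv < 1:
        raise FoldError("max_lv must be >= 1")
    accs = np.full((len(folds), max_lv), np.nan)
    for fi, fold in enumerate(folds):
        test_mask = patients.isin(fold).to_numpy()
        ytr, yte = y[~test_mask], y[test_mask]
        if len(set(ytr)) < 2 or len(yte) == 0:
            continue  # degenerate fold: skipped
        scaler = Scaler().fit(X.loc[~test_mask])
        Xtr = scaler.transform(X.loc[~test_mask]).to_numpy()
        Xte = scaler.transform(X.loc[test_mask]).to_numpy()
        a_max = min(max_lv, Xtr.shape[0] - 1, Xtr.shape[1])
        try:
            model = plsda_core.fit_pls(Xtr, ytr.to_numpy(), a_max)
        except RankError:
            a_max = max(a_max // 2, 1)
            model = plsda_core.fit_pls(Xtr, ytr.to_numpy(), a_max)
        thr = model.decision_threshold
        for a in range(1, a_max + 1):
            pred = plsda_core.predict(model, Xte, n_components=a)
            accs[fi, a - 1] = _binary_accuracy(pred, yte.to_numpy(), thr)
    if np.all(np.isnan(accs)):
        raise FoldError("all CV folds degenerate: cannot select LV count")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(accs, axis=0)
        n_ok = np.sum(~np.isnan(accs), axis=0)
        se = np.nanstd(accs, axis=0, ddof=0) / np.sqrt(np.maximum(n_ok, 1))
    valid = ~np.isnan(mean)
    best = int(np.nanargmax(mean))
    if one_se:
        cutoff = mean[best] - se[best]
        candidates = np.where(valid & (mean >= cutoff - 1e-12))[0]
        chosen = int(candidates.min()) + 1
    else:
        chosen = best + 1
    curve = pd.DataFrame({"n_lv": np.arange(1, max_lv + 1),
                          "cv_accuracy": mean, "se": se}).set_index("n_lv")
    return chosen, curve


# ---------------------------------------------------------------------------
# one-vs-rest training
# ---------------------------------------------------------------------------

@dataclass
class OvRModel:
    """Two-stage one-vs-rest model for a single target phenotype."""

    target_class: str
    n_lv: int
    selected_features: list[str]
    model: PLSModel             # stage 2, on the VIP-selected features
    scaler: Scaler              # stage 2 scaler
    stage1_model: PLSModel
    stage1_scaler: Scaler
    cv_accuracy: float
    accuracy_curve: pd.DataFrame | None = None

    def predict_raw(self, intensities: pd.DataFrame) -> pd.Series:
        """Continuous predicted value for samples on the raw intensity scale."""
        Z = self.scaler.transform(intensities)
        return pd.Series(plsda_core.predict(self.model, Z.to_numpy()),
                         index=intensities.index, name=self.target_class)


def train_ovr(X: pd.DataFrame, labels: pd.Series, patients: pd.Series,
              target_class: str, inner_folds: list[list[str]],
              max_lv: int = DEFAULT_MAX_LV, vip_threshold: float = 1.0,
              encoding: str = "01", one_se: bool = True) -> OvRModel:
    """Train one one-vs-rest model on a training partition.

    ``X`` is the raw-intensity training matrix (mixed patients already
    excluded); LV count comes from subject-wise inner CV, then stage 1 fits
    all features, VIP scores select features >= ``vip_threshold``, and stage
    2 recomputes the scaler and refits on the selection.
    """
    y = pd.Series(plsda_core.encode_labels(labels, target_class, encoding),
                  index=labels.index)
    n_lv, curve = select_n_lv(X, y, patients, inner_folds, max_lv,
                              one_se=one_se)
    scaler1 = Scaler().fit(X)
    Z1 = scaler1.transform(X)
    n_lv = min(n_lv, Z1.shape[0] - 1, Z1.shape[1])
    stage1 = plsda_core.fit_pls(Z1.to_numpy(), y.to_numpy(), n_lv,
                                encoding=encoding,
                                feature_ids=list(Z1.columns))
    vip = pd.Series(plsda_core.vip_scores(stage1), index=Z1.columns)
    selected = list(vip.index[vip >= vip_threshold])
    if not selected:
        raise ValueError(
            f"no feature reaches VIP >= {vip_threshold}; lower the threshold")
    scaler2 = Scaler().fit(X[selected])
    Z2 = scaler2.transform(X[selected])
    n_lv2 = min(n_lv, Z2.shape[1])
    stage2 = plsda_core.fit_pls(Z2.to_numpy(), y.to_numpy(), n_lv2,
                                encoding=encoding,
                                feature_ids=list(Z2.columns))
    cv_acc = float(curve["cv_accuracy"].loc[n_lv]) if n_lv in curve.index else np.nan
    return OvRModel(target_class=target_class, n_lv=n_lv2,
                    selected_features=selected, model=stage2, scaler=scaler2,
                    stage1_model=stage1, stage1_scaler=scaler1,
                    cv_accuracy=cv_acc, accuracy_curve=curve)


@dataclass
class PhenotypeEnsemble:
    """The three one-vs-rest models; predicts raw (y_C, y_H, y_R) triples."""

    models: dict[str, OvRModel]
    training_samples: list[str]
    seed: int

    def __post_init__(self) -> None:
        if set(self.models) != set(CLASSES):
            raise ValueError(f"ensemble needs exactly the models {CLASSES}")

    def predict_raw(self, intensities: pd.DataFrame) -> pd.DataFrame:
        """Raw continuous triple per sample (columns y_c, y_h, y_r)."""
        out = pd.DataFrame({
            "y_c": self.models["cholestatic"].predict_raw(intensities),
            "y_h": self.models["hepatocellular"].predict_raw(intensities),
            "y_r": self.models["recovered"].predict_raw(intensities),
        })
        return out

    def classify(self, intensities: pd.DataFrame) -> pd.Series:
        """Hard class per sample: argmax of the raw triple."""
        raw = self.predict_raw(intensities)
        idx = raw.to_numpy().argmax(axis=1)
        return pd.Series([CLASSES[{0: 0, 1: 1, 2: 2}[i]] for i in idx],
                         index=raw.index, name="predicted_class")


def train_ensemble(X: pd.DataFrame, labels: pd.Series, patients: pd.Series,
                   k_inner: int = 5, seed: int = 0,
                   max_lv: int = DEFAULT_MAX_LV, vip_threshold: float = 1.0,
                   encoding: str = "01", one_se: bool = True,
                   ) -> PhenotypeEnsemble:
    """Train the three one-vs-rest models on all non-mixed patients.

    ``labels`` holds the per-sample phenotype labels (cholestatic /
    hepatocellular / mixed / recovered / other); mixed-labelled patients and
    unlabelled samples are dropped from training.
    """
    excluded = mixed_type_patients(labels, patients)
    usable = labels.isin(CLASSES) & ~patients.isin(excluded)
    Xt, lt, pt = X.loc[usable], labels[usable], patients[usable]
    present = set(lt)
    if set(CLASSES) - present:
        raise ValueError(f"missing training classes: {set(CLASSES) - present}")
    k = min(k_inner, pt.nunique())
    inner = make_subject_folds(pt, k, seed)
    models = {c: train_ovr(Xt, lt, pt, c, inner, max_lv=max_lv,
                           vip_threshold=vip_threshold, encoding=encoding,
                           one_se=one_se)
              for c in CLASSES}
    return PhenotypeEnsemble(models=models, training_samples=list(Xt.index),
                             seed=seed)


# ---------------------------------------------------------------------------
# double cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    predictions: pd.DataFrame       # sample: y_c, y_h, y_r, predicted, label, fold
    confusion: pd.DataFrame
    accuracy: float
    balanced_accuracy: float
    per_class_accuracy: pd.Series   # binary OvR accuracy at the threshold
    n_lv_per_fold: pd.DataFrame


def double_cv_evaluate(X: pd.DataFrame, labels: pd.Series, patients: pd.Series,
                       k_outer: int = 5, k_inner: int = 5, seed: int = 0,
                       max_lv: int = DEFAULT_MAX_LV, vip_threshold: float = 1.0,
                       encoding: str = "01", one_se: bool = True) -> CVResult:
    """Subject-wise double CV estimate of out-of-sample performance.

    Outer folds hold out whole patients; each outer-training partition runs
    the complete inner pipeline (scaling, LV selection, VIP refit) blind to
    the held-out patients, then predicts them. Predictions are pooled over
    outer test folds only, so every usable sample is predicted exactly once.
    """
    excluded = mixed_type_patients(labels, patients)
    usable = labels.isin(CLASSES) & ~patients.isin(excluded)
    Xu, lu, pu = X.loc[usable], labels[usable], patients[usable]
    plan = build_fold_plan(pu, k_outer, k_inner, seed, exclude=excluded)
    rows, lv_rows = [], []
    for oi, fold in enumerate(plan.outer_folds):
        te = pu.isin(fold).to_numpy()
        Xtr, ltr, ptr = Xu.loc[~te], lu[~te], pu[~te]
        if len(set(ltr)) < 3:
            raise FoldError(
                f"outer fold {oi}: training partition lacks a class")
        inner = plan.inner_folds[oi]
        triple = {}
        for c in CLASSES:
            m = train_ovr(Xtr, ltr, ptr, c, inner, max_lv=max_lv,
                          vip_threshold=vip_threshold, encoding=encoding,
                          one_se=one_se)
            triple[c] = m
            lv_rows.append({"outer_fold": oi, "class": c, "n_lv": m.n_lv,
                            "n_features": len(m.selected_features)})
        Xte = Xu.loc[te]
        preds = pd.DataFrame({c: triple[c].predict_raw(Xte) for c in CLASSES})
        hard = preds.to_numpy().argmax(axis=1)
        for j, sid in enumerate(Xte.index):
            rows.append({"sample_id": sid, "fold": oi,
                         "y_c": preds.iloc[j, 0], "y_h": preds.iloc[j, 1],
                         "y_r": preds.iloc[j, 2],
                         "predicted": CLASSES[hard[j]],
                         "label": lu.loc[sid]})
    pred_df = pd.DataFrame(rows).set_index("sample_id")
    confusion = pd.crosstab(pred_df["label"], pred_df["predicted"]
                            ).reindex(index=CLASSES, columns=CLASSES,
                                      fill_value=0)
    accuracy = float((pred_df["label"] == pred_df["predicted"]).mean())
    recalls = [confusion.loc[c, c] / max(confusion.loc[c].sum(), 1)
               for c in CLASSES]
    thr = 0.5 if encoding == "01" else 0.0
    per_class = pd.Series({
        c: float(np.mean((pred_df[f"y_{c[0]}"] >= thr)
                         == (pred_df["label"] == c)))
        for c in CLASSES})
    return CVResult(predictions=pred_df, confusion=confusion,
                    accuracy=accuracy,
                    balanced_accuracy=float(np.mean(recalls)),
                    per_class_accuracy=per_class,
                    n_lv_per_fold=pd.DataFrame(lv_rows))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: PhenotypeEnsemble, out_dir: str | Path) -> None:
    """Write the ensemble as a directory of versioned JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"format": "dili-ternary-ensemble", "version": 1,
            "classes": list(CLASSES), "seed": ensemble.seed,
            "training_samples": ensemble.training_samples}
    (out / "ensemble.json").write_text(json.dumps(meta, indent=1))
    for c, m in ensemble.models.items():
        payload = {
            "target_class": m.target_class, "n_lv": m.n_lv,
            "cv_accuracy": m.cv_accuracy,
            "selected_features": m.selected_features,
            "model": plsda_core.model_to_dict(m.model),
            "scaler": {
                "half_min": m.scaler.half_min.to_dict(),
                "mean": m.scaler.mean.to_dict(),
                "sd": m.scaler.sd.to_dict(),
                "features": m.scaler.features,
                "excluded": m.scaler.excluded,
            },
        }
        (out / f"model_{c}.json").write_text(json.dumps(payload))


def load_ensemble(in_dir: str | Path) -> PhenotypeEnsemble:
    src = Path(in_dir)
    meta = json.loads((src / "ensemble.json").read_text())
    if meta.get("format") != "dili-ternary-ensemble":
        raise ValueError("not an ensemble directory")
    models = {}
    for c in meta["classes"]:
        payload = json.loads((src / f"model_{c}.json").read_text())
        sc = Scaler(half_min=pd.Series(payload["scaler"]["half_min"]),
                    mean=pd.Series(payload["scaler"]["mean"]),
                    sd=pd.Series(payload["scaler"]["sd"]),
                    features=payload["scaler"]["features"],
                    excluded=payload["scaler"]["excluded"])
        m = OvRModel(target_class=payload["target_class"],
                     n_lv=int(payload["n_lv"]),
                     selected_features=payload["selected_features"],
                     model=plsda_core.model_from_dict(payload["model"]),
                     scaler=sc,
                     stage1_model=plsda_core.model_from_dict(payload["model"]),
                     stage1_scaler=sc,
                     cv_accuracy=float(payload["cv_accuracy"]),
                     accuracy_curve=None)
        models[c] = m
    return PhenotypeEnsemble(models=models,
                             training_samples=meta["training_samples"],
                             seed=int(meta["seed"]))
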