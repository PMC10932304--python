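"""Synthetic DILI cohorts with known phenotype mixtures.

The generator emulates the statistical structure the analysis assumes, with
full ground truth, so every downstream stage is testable without patient
data:

* longitudinal plasma samples nested in patients, each sample carrying a
  latent mixture weight vector ``w = (w_C, w_H, w_R)`` on the simplex
  (cholestatic / hepatocellular / recovered poles);
* two disjoint informative metabolite blocks: a bile-acid-like block
  responding to ``w_C`` (mostly elevated) and a second block responding to
  ``w_H``, with a configurable fraction of each block depressed
  (glycerophospholipid-like); the recovered pole shifts nothing;
* log2 intensity model per feature *j*:
  ``baseline_j + w_C d_Cj + w_H d_Hj + drift(batch, injection) + N(0, noise_sd)``,
  exponentiated to the raw intensity scale, with missingness at random;
* within-batch multiplicative drift over injection order and pooled-QC
  injections at a fixed interval (QCs get the pooled mean profile + drift +
  technical noise);
* liver chemistry tied to the latent mixture: ``ALT = ULN_ALT (0.5 + g w_H
  + eps)`` and ``ALP = ULN_ALP (0.5 + g w_C + eps)`` with gain ``g``
  calibrated so pure poles exceed the clinical thresholds with probability
  >= 0.95; bilirubin rises with both injury weights.

Disease course: each patient starts at its pole (or, for mixed patients, at
a Dirichlet draw concentrated away from the recovered vertex) and resolves
abruptly at a per-patient recovery visit, after which the mixture sits near
the recovered vertex — clinical resolution between visits, which keeps
samples away from ambiguous mid-trajectory mixtures. A clinician-style label
per sample (``recovered`` when ``w_R >= 0.75``, else the patient's latent
type) emulates the expert-plus-R-score sample classification the ensemble
trains on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import Cohort, PeakTable, SampleRecord, join_cohort

PATIENT_TYPES = ("pure_c", "pure_h", "recovered", "mixed")
TYPE_TO_LABEL = {"pure_c": "cholestatic", "pure_h": "hepatocellular",
                 "mixed": "mixed", "recovered": "recovered"}


@dataclass
class SimulationConfig:
    """Study-condition parameters for cohort simulation.

    Defaults mirror the cohort the analysis targets: ~60 patients with 2-5
    longitudinal samples each, 828 LC-MS features with two ~60-feature
    informative blocks, a mean absolute log2 effect of 1.5 at the pure poles,
    residual log2 noise 0.5, two acquisition batches with mild drift and a
    pooled QC every 10 injections.
    """

    n_patients: int = 60
    timepoints_min: int = 2
    timepoints_max: int = 5
    class_mix: dict[str, float] = field(default_factory=lambda: {
        "pure_c": 0.25, "pure_h": 0.20, "recovered": 0.30, "mixed": 0.25})
    n_features: int = 828
    n_informative_c: int = 60
    n_informative_h: int = 60
    frac_down: float = 0.3          # fraction of each block shifted down
    effect_size: float = 1.5        # mean |log2 fold-change| at the pole
    n_batches: int = 2
    drift_amplitude: float = 0.10
    qc_every: int = 10
    n_blanks: int = 2
    missing_rate: float = 0.05
    noise_sd: float = 0.5           # study-sample residual, log2
    qc_noise_sd: float = 0.05       # QC technical replicate noise, log2
    clinical_gain: float = 4.0      # g in ALT/ALP link
    clinical_noise_sd: float = 0.15
    dirichlet_alpha: tuple[float, float, float] = (4.0, 4.0, 2.0)
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if set(self.class_mix) != set(PATIENT_TYPES):
            raise ValueError(f"class_mix must have keys {PATIENT_TYPES}")
        if self.n_informative_c + self.n_informative_h > self.n_features:
            raise ValueError("informative blocks exceed n_features")
        for name in ("frac_down", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.timepoints_min < 1 or self.timepoints_max < self.timepoints_min:
            raise ValueError("invalid timepoint range")
        if min(self.n_patients, self.n_batches, self.qc_every) < 1:
            raise ValueError("n_patients, n_batches, qc_every must be >= 1")


@dataclass
class GroundTruth:
    """Latent mixture weights per sample and the informative index sets."""

    weights: pd.DataFrame            # index sample_id: w_c, w_h, w_r
    informative_c: list[str]
    informative_h: list[str]
    patient_type: pd.Series          # index patient_id


def _allocate_counts(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of patients to types."""
    raw = {k: n * v for k, v in mix.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort plus ground truth. Deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_features
    feature_ids = [f"mz{100 + i:04d}_rt{(i % 600) / 100:.2f}_pos"
                   for i in range(p)]
    idx_c = np.arange(config.n_informative_c)
    idx_h = np.arange(config.n_informative_c,
                      config.n_informative_c + config.n_informative_h)

    # signature blocks: magnitudes average effect_size; a fraction depressed
    def _block(idx: np.ndarray) -> np.ndarray:
        delta = np.zeros(p)
        mag = config.effect_size * rng.uniform(0.5, 1.5, size=idx.size)
        sign = np.ones(idx.size)
        n_down = int(round(config.frac_down * idx.size))
        if n_down:
            sign[rng.choice(idx.size, size=n_down, replace=False)] = -1.0
        delta[idx] = sign * mag
        return delta

    delta_c, delta_h = _block(idx_c), _block(idx_h)
    baseline = rng.uniform(14.0, 20.0, size=p)   # log2 raw-intensity scale

    # ---- patients, trajectories, ground-truth weights --------------------
    counts = _allocate_counts(config.n_patients, config.class_mix)
    types = [t for t in PATIENT_TYPES for _ in range(counts[t])]
    rng.shuffle(types)
    patient_ids = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    patient_type = pd.Series(types, index=patient_ids, name="patient_type")

    sample_rows = []   # (sample_id, patient_id, timepoint, w)
    for pid, ptype in patient_type.items():
        n_tp = int(rng.integers(config.timepoints_min,
                                config.timepoints_max + 1))
        if ptype == "recovered":
            w0 = np.array([0.0, 0.0, 1.0])
            recovery_visit = 1
        else:
            if ptype == "pure_c":
                w0 = np.array([rng.uniform(0.85, 1.0), 0.0, 0.0])
                w0[2] = 1.0 - w0[0]
            elif ptype == "pure_h":
                w0 = np.array([0.0, rng.uniform(0.85, 1.0), 0.0])
                w0[2] = 1.0 - w0[1]
            else:
                w0 = rng.dirichlet(config.dirichlet_alpha)
            # resolves abruptly at a uniformly drawn visit (possibly never
            # within the sampling window)
            recovery_visit = int(rng.integers(2, n_tp + 2))
        for t in range(1, n_tp + 1):
            if ptype == "recovered":
                f = 1.0
            elif t >= recovery_visit:
                f = rng.uniform(0.90, 1.0)
            else:
                f = 0.05 * (t - 1)
            w = (1.0 - f) * w0 + f * np.array([0.0, 0.0, 1.0])
            w = np.clip(w, 0.0, None)
            w /= w.sum()
            sample_rows.append((f"{pid}-t{t}", pid, t, w))

    n_study = len(sample_rows)
    weights = pd.DataFrame(
        [w for *_, w in sample_rows],
        index=pd.Index([s for s, *_ in sample_rows], name="sample_id"),
        columns=["w_c", "w_h", "w_r"])

    # ---- study-sample expected log profiles ------------------------------
    W = weights.to_numpy()
    study_log = (baseline[None, :]
                 + np.outer(W[:, 0], delta_c)
                 + np.outer(W[:, 1], delta_h))
    pooled_mean = study_log.mean(axis=0)   # QC = pooled plasma profile

    # ---- injection layout: batches, order, interleaved QCs ---------------
    order = rng.permutation(n_study)
    batches = np.array_split(order, config.n_batches)
    all_ids, all_batch, all_inj, all_role, log_rows = [], [], [], [], []
    qc_counter = blank_counter = 0
    for bi, members in enumerate(batches):
        batch_name = f"B{bi + 1}"
        seq: list[tuple[str, np.ndarray, float]] = []  # (role/id, logμ, noise_sd)
        for k, si in enumerate(members):
            if k % config.qc_every == 0:
                qc_counter += 1
                seq.append((f"QC{qc_counter:03d}", pooled_mean,
                            config.qc_noise_sd))
            sid, *_ = sample_rows[si]
            seq.append((sid, study_log[si], config.noise_sd))
        qc_counter += 1
        seq.append((f"QC{qc_counter:03d}", pooled_mean, config.qc_noise_sd))
        for _ in range(config.n_blanks if bi == 0 else 0):
            blank_counter += 1
            # blanks: background at ~1% of typical signal
            seq.append((f"BLANK{blank_counter:02d}", baseline - 7.0, 0.3))
        n_in_batch = len(seq)
        drift_dir = rng.choice([-1.0, 1.0], size=p)
        for pos, (sid, mu, sd) in enumerate(seq, start=1):
            frac = (pos - 1) / max(n_in_batch - 1, 1)
            drift = np.log2(1.0 + config.drift_amplitude * frac) * drift_dir
            log_rows.append(mu + drift + rng.normal(0.0, sd, size=p))
            all_ids.append(sid)
            all_batch.append(batch_name)
            all_inj.append(pos)
            all_role.append("qc" if sid.startswith("QC")
                            else "blank" if sid.startswith("BLANK")
                            else "study")

    intens = np.power(2.0, np.asarray(log_rows))
    if config.missing_rate > 0:
        mask = rng.random(intens.shape) < config.missing_rate
        intens[mask] = np.nan
    intensities = pd.DataFrame(intens,
                               index=pd.Index(all_ids, name="sample_id"),
                               columns=feature_ids)
    peak_table = PeakTable(
        intensities=intensities,
        batch=pd.Series(all_batch, index=intensities.index, name="batch"),
        injection_order=pd.Series(all_inj, index=intensities.index,
                                  name="injection_order", dtype=int),
        role=pd.Series(all_role, index=intensities.index, name="role"))

    # ---- clinical chemistry tied to the latent mixture -------------------
    g, csd = config.clinical_gain, config.clinical_noise_sd
    records = []
    for sid, pid, t, w in sample_rows:
        alt = 56.0 * max(0.5 + g * w[1] + rng.normal(0, csd), 0.01)
        alp = 147.0 * max(0.5 + g * w[0] + rng.normal(0, csd), 0.01)
        bil = 1.2 * max(0.4 + 2.0 * w[0] + 0.5 * w[1] + rng.normal(0, 0.1),
                        0.01)
        label = ("recovered" if w[2] >= 0.75
                 else TYPE_TO_LABEL[patient_type[pid]])
        records.append(SampleRecord(
            sample_id=sid, patient_id=pid, timepoint_index=t,
            alt=round(alt, 1), alp=round(alp, 1), bilirubin=round(bil, 2),
            days_from_onset=14 * (t - 1), drug="synthetic_drug",
            clinician_label=label))

    cohort, report = join_cohort(peak_table, records)
    assert report.clean
    truth = GroundTruth(weights=weights,
                        informative_c=[feature_ids[i] for i in idx_c],
                        informative_h=[feature_ids[i] for i in idx_h],
                        patient_type=patient_type)
    return cohort, truth


def corrupt_with_drift(peak_table: PeakTable, amplitude: float,
                       seed: int = 0) -> PeakTable:
    """Impose a linear within-batch drift: x1 at batch start, x(1+amplitude)
    at the last injection. A corruption fixture for testing the correction;
    requires QC rows (otherwise the correction would be untestable)."""
    if not (peak_table.role == "qc").any():
        raise ValueError("peak table has no QC rows; drift would be "
                         "uncorrectable")
    out = peak_table.intensities.copy()
    for b in peak_table.batch.unique():
        m = peak_table.batch == b
        inj = peak_table.injection_order[m].to_numpy(float)
        lo, hi = inj.min(), inj.max()
        frac = (inj - lo) / max(hi - lo, 1.0)
        factor = 1.0 + amplitude * frac
        out.loc[m] = out.loc[m].to_numpy() * factor[:, None]
    return PeakTable(out, peak_table.batch.copy(),
                     peak_table.injection_order.copy(),
                     peak_table.role.copy())
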