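"""R-score computation and rule-based clinical DILI classification.

The R score compares alanine aminotransferase (ALT, hepatocyte marker) with
alkaline phosphatase (ALP, cholangiocyte/bile-duct marker), each expressed as
a multiple of its upper limit of normal (ULN)::

    R = (ALT / ULN_ALT) / (ALP / ULN_ALP)

Clinical phenotype rules (hepatology convention, evaluated in order):

1. recovered       — ALT < ULN_ALT and ALP < ULN_ALP
2. hepatocellular  — ALT >= ULN_ALT and R >= 5
3. cholestatic     — ALP >= ULN_ALP and R < 2
4. mixed           — 2 <= R < 5 and ALT >= ULN_ALT and ALP >= ULN_ALP
5. unclassifiable  — anything left (the rules are not exhaustive; samples in
   the gaps are surfaced rather than coerced)

Defaults: ULN_ALT = 56 U/L, ULN_ALP = 147 U/L, ULN bilirubin = 1.2 mg/dL.
The hepatocellular boundary is R >= 5 by default; ``strict_hepatocellular``
switches to the strict R > 5 reading. A ``recovered_requires_bilirubin``
variant additionally demands bilirubin < ULN for the recovered call; both
variants are reported by :func:`classify_cohort`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort_io import Cohort, SampleRecord

LABELS = ("cholestatic", "hepatocellular", "mixed", "recovered",
          "unclassifiable")


class UndefinedRScoreError(ZeroDivisionError):
    """ALP of zero makes the R score undefined."""


@dataclass(frozen=True)
class ClinicalThresholds:
    """Upper limits of normal for the liver panel."""

    uln_alt: float = 56.0     # U/L
    uln_alp: float = 147.0    # U/L
    uln_bil: float = 1.2      # mg/dL
    strict_hepatocellular: bool = False   # R > 5 instead of R >= 5
    recovered_requires_bilirubin: bool = False

    def __post_init__(self) -> None:
        if min(self.uln_alt, self.uln_alp, self.uln_bil) <= 0:
            raise ValueError("thresholds must be strictly positive")


@dataclass(frozen=True)
class ClinicalCall:
    r_score: float | None
    label: str
    reason: str = ""


def r_score(alt: float, alp: float,
            thresholds: ClinicalThresholds = ClinicalThresholds()) -> float:
    """(ALT/ULN_ALT) / (ALP/ULN_ALP); raises for ALP = 0."""
    if alt < 0 or alp < 0:
        raise ValueError("ALT and ALP must be nonnegative")
    if alp == 0:
        raise UndefinedRScoreError("R score undefined for ALP = 0")
    return (alt / thresholds.uln_alt) / (alp / thresholds.uln_alp)


def classify_clinical(record: SampleRecord,
                      thresholds: ClinicalThresholds = ClinicalThresholds(),
                      ) -> ClinicalCall:
    """Apply the ordered phenotype rules to one sample's chemistry."""
    alt, alp = record.alt, record.alp
    if alt is None or alp is None:
        return ClinicalCall(None, "unclassifiable", "missing ALT or ALP")
    try:
        r = r_score(alt, alp, thresholds)
    except UndefinedRScoreError:
        return ClinicalCall(None, "unclassifiable", "ALP = 0, R undefined")
    if alt < thresholds.uln_alt and alp < thresholds.uln_alp:
        if (thresholds.recovered_requires_bilirubin
                and record.bilirubin is not None
                and record.bilirubin >= thresholds.uln_bil):
            return ClinicalCall(r, "unclassifiable",
                                "enzymes normal but bilirubin elevated")
        return ClinicalCall(r, "recovered")
    hep = (r > 5) if thresholds.strict_hepatocellular else (r >= 5)
    if alt >= thresholds.uln_alt and hep:
        return ClinicalCall(r, "hepatocellular")
    if alp >= thresholds.uln_alp and r < 2:
        return ClinicalCall(r, "cholestatic")
    if 2 <= r < 5 and alt >= thresholds.uln_alt and alp >= thresholds.uln_alp:
        return ClinicalCall(r, "mixed")
    return ClinicalCall(r, "unclassifiable", "outside the rule set")


def classify_cohort(cohort: Cohort,
                    thresholds: ClinicalThresholds = ClinicalThresholds(),
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample clinical calls for every study sample, plus label counts.

    Returns a DataFrame indexed by sample_id with columns ``r_score``,
    ``label``, ``label_bil`` (the bilirubin-gated recovered variant),
    ``reason`` and ``clinician_label`` (pass-through for comparison), and a
    Series of counts per label.
    """
    thr_bil = ClinicalThresholds(
        thresholds.uln_alt, thresholds.uln_alp, thresholds.uln_bil,
        thresholds.strict_hepatocellular, recovered_requires_bilirubin=True)
    rows = []
    for rec in cohort.records:
        call = classify_clinical(rec, thresholds)
        call_bil = classify_clinical(rec, thr_bil)
        rows.append({"sample_id": rec.sample_id, "r_score": call.r_score,
                     "label": call.label, "label_bil": call_bil.label,
                     "reason": call.reason,
                     "clinician_label": rec.clinician_label})
    if not rows:
        table = pd.DataFrame(
            columns=["r_score", "label", "label_bil", "reason",
                     "clinician_label"],
            index=pd.Index([], name="sample_id"))
    else:
        table = pd.DataFrame(rows).set_index("sample_id")
    counts = table["label"].value_counts().reindex(LABELS, fill_value=0)
    return table, counts
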