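"""Expression analysis: RPM normalization, tissue-bias and tissue-specific
calls, and stem-loop qRT-PCR relative quantification (2^-ddCt).

A unit (miRNA or family) is *tissue-biased* when its normalized abundance
(reads per million clean reads) in one tissue is at least twice that in
each of the other tissues; it is additionally *tissue-specific* when its
raw count is zero everywhere else.  The 2x boundary is inclusive and
all-zero rows are unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BIAS_FACTOR = 2.0


@dataclass
class ExpressionMatrix:
    counts: pd.DataFrame        # rows: units, columns: tissues (raw counts)
    library_totals: dict        # tissue -> total clean reads

    @property
    def rpm(self) -> pd.DataFrame:
        totals = pd.Series(self.library_totals)
        return self.counts / totals[self.counts.columns] * 1e6


def to_rpm(counts: pd.DataFrame, library_totals: dict) -> ExpressionMatrix:
    """Reads-per-million normalization against per-library clean totals."""
    missing = set(counts.columns) - set(library_totals)
    if missing:
        raise ValueError(f"no library total for tissue(s) {sorted(missing)}")
    for tissue in counts.columns:
        if library_totals[tissue] <= 0:
            raise ValueError(f"non-positive library total for {tissue!r}")
    return ExpressionMatrix(counts=counts.astype(float), library_totals=dict(library_totals))


def family_aggregate(counts: pd.DataFrame, family_map: dict) -> pd.DataFrame:
    """Sum member counts per family and tissue (raw counts, pre-RPM)."""
    missing = [u for u in counts.index if u not in family_map]
    if missing:
        raise ValueError(f"units without family assignment: {missing[:3]}")
    fam = counts.groupby(counts.index.map(family_map)).sum()
    fam.index.name = "family"
    return fam


@dataclass
class BiasCall:
    unit: str
    label: str                  # "<tissue>-biased" or "unbiased"
    specific_to: str | None = None
    rpm: dict | None = None


def call_bias(matrix: ExpressionMatrix) -> list[BiasCall]:
    """Call per-unit tissue bias on the RPM matrix.

    Biased: RPM in one tissue >= 2x the RPM of each other tissue, with the
    focal RPM strictly positive.  Specific: raw count zero in every other
    tissue.  All-zero units and units where no tissue clears the factor
    are unbiased.
    """
    rpm = matrix.rpm
    tissues = list(rpm.columns)
    if len(tissues) < 2:
        raise ValueError("bias calls need at least two tissues")
    calls = []
    for unit, row in rpm.iterrows():
        label, specific = "unbiased", None
        for t in tissues:
            others = [row[o] for o in tissues if o != t]
            if row[t] > 0 and all(row[t] >= BIAS_FACTOR * v for v in others):
                label = f"{t}-biased"
                raw = matrix.counts.loc[unit]
                if all(raw[o] == 0 for o in tissues if o != t):
                    specific = t
                break
        calls.append(BiasCall(unit=unit, label=label, specific_to=specific,
                              rpm=row.to_dict()))
    return calls


def bias_table(calls: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"unit": c.unit, "label": c.label, "specific_to": c.specific_to or "",
             **{f"rpm_{k}": v for k, v in (c.rpm or {}).items()}}
            for c in calls
        ]
    )


def biased_units(calls: list, tissue: str) -> list:
    return sorted(c.unit for c in calls if c.label == f"{tissue}-biased")


@dataclass
class DdctResult:
    assay: str
    sample: str
    calibrator: str
    ct_target: float
    ct_reference: float
    delta_ct: float
    delta_delta_ct: float
    rq: float


def ddct(ct_table: pd.DataFrame, assay: str, reference_assays: list,
         calibrator_sample: str) -> list[DdctResult]:
    """Relative quantification by the 2^-ddCt method.

    Replicate Cts are averaged per (assay, sample); the reference Ct is the
    arithmetic mean of the reference assays' mean Cts (equivalent to a
    geometric mean of their linear quantities).  dCt = Ct_assay - Ct_ref;
    ddCt = dCt_sample - dCt_calibrator; RQ = 2^-ddCt, so the calibrator
    sample always has RQ 1.
    """
    means = ct_table.groupby(["assay", "sample"])["Ct"].mean()

    def mean_ct(a: str, s: str) -> float:
        if (a, s) not in means.index:
            raise ValueError(f"no Ct replicates for assay {a!r} in sample {s!r}")
        return float(means[(a, s)])

    samples = sorted(ct_table["sample"].unique())
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in table")

    def delta_ct(sample: str) -> tuple[float, float, float]:
        ct_t = mean_ct(assay, sample)
        ct_r = float(np.mean([mean_ct(r, sample) for r in reference_assays]))
        return ct_t, ct_r, ct_t - ct_r

    _, _, dct_cal = delta_ct(calibrator_sample)
    results = []
    for sample in samples:
        ct_t, ct_r, dct = delta_ct(sample)
        ddct_val = dct - dct_cal
        results.append(
            DdctResult(
                assay=assay, sample=sample, calibrator=calibrator_sample,
                ct_target=ct_t, ct_reference=ct_r, delta_ct=dct,
                delta_delta_ct=ddct_val, rq=float(2.0 ** (-ddct_val)),
            )
        )
    return results
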