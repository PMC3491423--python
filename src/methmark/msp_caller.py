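"""Rule-based methylation calling from high-throughput MSP readouts.

Methylation-specific PCR primers amplify only methylated (bisulfite
converted) template, so a qualifying amplicon implies methylation.  A
reaction is called methylated when all four rules hold against the
assay's positive control:

1. quantification cycle Cq strictly below 35,
2. melting temperature within 2 degrees C of the positive control,
3. amplicon length within 10 bp of the positive control,
4. electrophoresis band height strictly above 20 (instrument units).

Control gating: a sample is valid only if its ACTB control reaction
amplifies; a positive no-template control invalidates the affected
assay across the whole run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

METHYLATED = "M"
UNMETHYLATED = "U"
INVALID = "NA"


@dataclass(frozen=True)
class CallThresholds:
    """Call rule thresholds; strictness follows the rule set exactly
    (< for Cq, > for height, <= for the control deltas)."""

    cq_max: float = 35.0
    dtm_max: float = 2.0
    dsize_max: float = 10.0
    height_min: float = 20.0
    use_size_rule: bool = True
    use_height_rule: bool = True


@dataclass(frozen=True)
class ControlRef:
    """Per-assay positive-control melting temperature and amplicon size."""

    assay: str
    tm_celsius: float
    amplicon_bp: float


def call_assay(
    cq: float,
    tm_celsius: float,
    amplicon_bp: float,
    band_height: float,
    control: ControlRef | None,
    thresholds: CallThresholds = CallThresholds(),
) -> str:
    """Call one reaction methylated/unmethylated against its control."""
    if control is None:
        return INVALID
    t = thresholds
    ok = (
        cq < t.cq_max
        and abs(tm_celsius - control.tm_celsius) <= t.dtm_max
    )
    if ok and t.use_size_rule:
        ok = abs(amplicon_bp - control.amplicon_bp) <= t.dsize_max
    if ok and t.use_height_rule:
        ok = band_height > t.height_min
    return METHYLATED if ok else UNMETHYLATED


def call_matrix(
    readouts: pd.DataFrame,
    controls: dict[str, ControlRef],
    thresholds: CallThresholds = CallThresholds(),
) -> pd.DataFrame:
    """Call every (assay, sample) readout; assays x samples matrix.

    ``readouts`` columns: assay, sample, cq (inf = no amplification),
    tm_celsius, amplicon_bp, band_height.  Readouts of assays without a
    control are invalid.
    """
    calls: dict[tuple[str, str], str] = {}
    for r in readouts.itertuples():
        cq = math.inf if pd.isna(r.cq) else float(r.cq)
        calls[(r.assay, r.sample)] = call_assay(
            cq,
            float(r.tm_celsius),
            float(r.amplicon_bp),
            float(r.band_height),
            controls.get(r.assay),
            thresholds,
        )
    assays = sorted({a for a, _ in calls})
    samples = sorted({s for _, s in calls})
    out = pd.DataFrame(INVALID, index=assays, columns=samples)
    for (a, s), c in calls.items():
        out.loc[a, s] = c
    return out


def validate_run(
    actb_readouts: pd.DataFrame,
    ntc_readouts: pd.DataFrame,
    actb_cq_max: float = 35.0,
) -> tuple[pd.Series, list[str]]:
    """Control gating for one run.

    A sample is valid iff its ACTB reaction amplifies (Cq below
    ``actb_cq_max``).  Any amplifying no-template control flags its
    assay: those assays' calls are invalid for the whole run.  Returns
    (per-sample validity, list of flagged assays).
    """
    cq = actb_readouts["cq"].fillna(math.inf).astype(float)
    sample_valid = pd.Series(
        (cq < actb_cq_max).to_numpy(), index=actb_readouts["sample"].to_numpy()
    )
    ntc_cq = ntc_readouts["cq"].fillna(math.inf).astype(float)
    flagged = sorted(ntc_readouts.loc[(ntc_cq < actb_cq_max).to_numpy(), "assay"].unique())
    return sample_valid, flagged


def apply_validity(
    matrix: pd.DataFrame,
    sample_valid: pd.Series | None = None,
    flagged_assays: list[str] | None = None,
) -> pd.DataFrame:
    """Mark calls of invalid samples / flagged assays as invalid."""
    out = matrix.copy()
    if sample_valid is not None:
        bad = [s for s in out.columns if not sample_valid.get(s, True)]
        out.loc[:, bad] = INVALID
    if flagged_assays:
        out.loc[[a for a in flagged_assays if a in out.index], :] = INVALID
    return out


def count_events(matrix: pd.DataFrame) -> pd.Series:
    """Number of methylation events (methylated calls) per sample;
    invalid entries are excluded."""
    return (matrix == METHYLATED).sum(axis=0)


_BINS = [
    (0.75, ">=75%"),
    (0.50, "50-75%"),
    (0.10, "10-50%"),
    (0.00, "<10%"),
]


def assay_prevalence(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-assay methylated fraction among valid calls, with prevalence
    bin (lower edges inclusive).  Assays with no valid call get NA."""
    meth = (matrix == METHYLATED).sum(axis=1)
    unmeth = (matrix == UNMETHYLATED).sum(axis=1)
    total = meth + unmeth
    frac = meth / total.replace(0, np.nan)

    def bin_of(f: float) -> str | None:
        if pd.isna(f):
            return None
        return next(label for lo, label in _BINS if f >= lo)

    return pd.DataFrame(
        {"n_methylated": meth, "n_valid": total, "fraction": frac,
         "bin": frac.map(bin_of)}
    )


def filter_informative(matrix: pd.DataFrame, min_count: int = 3) -> list[str]:
    """Assays methylated in at least ``min_count`` samples AND
    unmethylated in at least ``min_count`` samples."""
    meth = (matrix == METHYLATED).sum(axis=1)
    unmeth = (matrix == UNMETHYLATED).sum(axis=1)
    keep = (meth >= min_count) & (unmeth >= min_count)
    return list(matrix.index[keep])
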