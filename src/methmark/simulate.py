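"""Synthetic study generator with planted ground truth.

Every input the pipeline consumes can be generated here: a clinical
cohort split over three prognostic groups, a ground-truth methylation
call matrix with per-group marker frequencies mirroring the validation
cohort, raw MSP readouts realising the four call rules with tunable
error, paired expression matrices with detection calls for the
demethylation (DAC) re-expression screen, per-cell-line methylation
peak sets with promoter-region fragment counts, promoter sequences with
planted families, tumor expression matrices, survival times with
methylation-dependent hazards, and qPCR Cq tables.

All generators are deterministic under their seed.  Readout
distributions are truncated so that, at zero flip rate, truly
methylated readouts always satisfy the four call rules and truly
unmethylated readouts always violate at least one — the noiseless
round trip recovers the truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_io, msp_caller
from .core_io import GenomicInterval
from .survival import HR_DOD, HR_SURV, LR_SURV

# Per-group methylation frequencies of the eight markers of the
# validation cohort (fractions methylated in LR-SURV / HR-SURV / HR-DOD).
VALIDATION_MARKER_FREQS: dict[str, dict[str, float]] = {
    "KRT19": {LR_SURV: 0 / 31, HR_SURV: 14 / 30, HR_DOD: 9 / 28},
    "FAS": {LR_SURV: 1 / 31, HR_SURV: 8 / 30, HR_DOD: 6 / 28},
    "PRPH": {LR_SURV: 14 / 31, HR_SURV: 24 / 30, HR_DOD: 19 / 28},
    "CNR1": {LR_SURV: 2 / 31, HR_SURV: 10 / 30, HR_DOD: 10 / 28},
    "QPCT": {LR_SURV: 18 / 31, HR_SURV: 25 / 30, HR_DOD: 24 / 28},
    "HIST1H3C": {LR_SURV: 0 / 31, HR_SURV: 2 / 30, HR_DOD: 6 / 28},
    "ACSS3": {LR_SURV: 0 / 31, HR_SURV: 14 / 30, HR_DOD: 7 / 28},
    "GRB10": {LR_SURV: 6 / 31, HR_SURV: 13 / 30, HR_DOD: 11 / 28},
}


@dataclass(frozen=True)
class TruthConfig:
    """Cohort sizes, marker frequencies and planted effects.

    Defaults reproduce the validation cohort: 31 low-risk survivors,
    28 high-risk deceased, 30 high-risk survivors, and the eight-marker
    frequency table.
    """

    n_lr_surv: int = 31
    n_hr_dod: int = 28
    n_hr_surv: int = 30
    marker_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: dict(VALIDATION_MARKER_FREQS)
    )
    mna_specific_markers: frozenset[str] = frozenset({"HIST1H3C", "ACSS3"})
    prognostic_markers: tuple[str, ...] = ("CNR1", "ACSS3", "HIST1H3C", "PRPH")
    hazard_multiplier: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_lr_surv, self.n_hr_dod, self.n_hr_surv) < 0:
            raise ValueError("group sizes must be non-negative")
        if self.hazard_multiplier <= 0:
            raise ValueError("hazard multiplier must be positive")
        groups = {LR_SURV, HR_SURV, HR_DOD}
        for marker, freqs in self.marker_freqs.items():
            if set(freqs) != groups:
                raise ValueError(f"{marker}: frequencies must cover all groups")
            if any(not 0 <= p <= 1 for p in freqs.values()):
                raise ValueError(f"{marker}: probabilities outside [0, 1]")


@dataclass(frozen=True)
class NoiseParams:
    flip_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.flip_rate <= 1:
            raise ValueError("flip rate outside [0, 1]")


# ---------------------------------------------------------------------------
# Clinical cohort


def _draw_lr(rng: np.random.Generator) -> dict:
    if rng.random() < 0.7:
        stage = str(rng.choice(["1", "2"]))
        age = int(rng.integers(30, 2000))
    else:
        stage = "3"
        age = int(rng.integers(30, 360))
    return {"stage": stage, "mycn": "single_copy", "age_days": age}


def _draw_hr(rng: np.random.Generator) -> dict:
    u = rng.random()
    if u < 0.3:
        return {
            "stage": str(rng.choice(["2", "3"])),
            "mycn": "amplified",
            "age_days": int(rng.integers(30, 2000)),
        }
    if u < 0.5:
        return {
            "stage": "4",
            "mycn": "amplified",
            "age_days": int(rng.integers(30, 360)),
        }
    return {
        "stage": "4",
        "mycn": str(rng.choice(["amplified", "single_copy"])),
        "age_days": int(rng.integers(370, 2000)),
    }


def gen_clinical_cohort(cfg: TruthConfig) -> pd.DataFrame:
    """Clinical records satisfying their prognostic group's criteria."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    idx = 0
    for group, n in (
        (LR_SURV, cfg.n_lr_surv),
        (HR_DOD, cfg.n_hr_dod),
        (HR_SURV, cfg.n_hr_surv),
    ):
        for _ in range(n):
            idx += 1
            if group == LR_SURV:
                base = _draw_lr(rng)
                outcome = "alive"
                fup = int(rng.integers(1001, 2400))
                relapse = pd.NA
            elif group == HR_SURV:
                base = _draw_hr(rng)
                outcome = "alive"
                fup = int(rng.integers(1001, 2400))
                relapse = pd.NA
            else:
                base = _draw_hr(rng)
                outcome = "dod"
                fup = int(rng.integers(100, 1800))
                relapse = (
                    int(rng.integers(30, fup)) if rng.random() < 0.5 else pd.NA
                )
            rows.append(
                {
                    "sample": f"NB{idx:03d}",
                    **base,
                    "outcome": outcome,
                    "followup_days": fup,
                    "relapse_days": relapse,
                    "risk_group": group,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=core_io.CLINICAL_COLUMNS + ["risk_group"],
    )
    if len(df):
        core_io.validate_clinical(df)
    return df


def gen_truth_calls(cfg: TruthConfig, clinical: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth methylation matrix (markers x samples, 'M'/'U')
    drawn per marker from its group frequency."""
    rng = np.random.default_rng(cfg.seed + 1)
    markers = sorted(cfg.marker_freqs)
    samples = clinical["sample"].to_numpy()
    groups = clinical["risk_group"].to_numpy()
    mat = np.empty((len(markers), len(samples)), dtype=object)
    for i, m in enumerate(markers):
        p = np.array([cfg.marker_freqs[m][g] for g in groups])
        mat[i] = np.where(rng.random(len(samples)) < p, "M", "U")
    return pd.DataFrame(mat, index=markers, columns=samples)


def gen_signature_truth(
    clinical: pd.DataFrame,
    signature: list[str],
    seed: int = 0,
    p_in: float = 0.95,
    p_out: float = 0.05,
) -> pd.DataFrame:
    """Truth calls for a complementary prognostic signature.

    The HR-DOD patients are partitioned into one block per signature
    marker; each marker is methylated with probability ``p_in`` inside
    its block and ``p_out`` elsewhere.  Because every marker tags a
    different subset of the deceased patients, a classifier needs the
    whole signature — mimicking a marker panel whose members carry
    complementary rather than redundant prognostic information.
    """
    rng = np.random.default_rng(seed)
    samples = clinical["sample"].to_numpy()
    groups = clinical["risk_group"].to_numpy()
    dod = np.array([s for s, g in zip(samples, groups) if g == HR_DOD])
    blocks = np.array_split(dod, len(signature))
    mat = {}
    for m, block in zip(signature, blocks):
        members = set(block)
        p = np.array([p_in if s in members else p_out for s in samples])
        mat[m] = np.where(rng.random(len(samples)) < p, "M", "U")
    return pd.DataFrame(mat, index=samples).T


# ---------------------------------------------------------------------------
# MSP readouts


@dataclass
class MSPReadoutSet:
    readouts: pd.DataFrame      # assay, sample, cq, tm_celsius, amplicon_bp, band_height
    controls: dict[str, msp_caller.ControlRef]
    actb: pd.DataFrame          # ACTB control reactions per sample
    ntc: pd.DataFrame           # no-template control per assay


def _methylated_readout(rng, ctrl: msp_caller.ControlRef) -> dict:
    # truncated so every call rule is satisfied
    cq = float(np.clip(rng.normal(30, 2), 15.1, 34.5))
    tm = ctrl.tm_celsius + float(np.clip(rng.normal(0, 0.5), -1.8, 1.8))
    size = ctrl.amplicon_bp + int(np.clip(round(rng.normal(0, 2)), -8, 8))
    height = float(max(25.0, rng.lognormal(4.5, 0.5)))
    return {"cq": cq, "tm_celsius": tm, "amplicon_bp": size, "band_height": height}


def _unmethylated_readout(rng, ctrl: msp_caller.ControlRef) -> dict:
    # no amplification 80% of the time; otherwise late, off-melting product
    cq = np.inf if rng.random() < 0.8 else float(max(35.2, rng.normal(38, 1)))
    offset = max(2.2, abs(rng.normal(4, 1))) * (1 if rng.random() < 0.5 else -1)
    tm = ctrl.tm_celsius + offset
    size = ctrl.amplicon_bp + int(np.clip(round(rng.normal(0, 2)), -8, 8))
    height = float(rng.lognormal(2.0, 0.5))
    return {"cq": cq, "tm_celsius": tm, "amplicon_bp": size, "band_height": height}


def gen_msp_readouts(
    truth: pd.DataFrame, noise: NoiseParams = NoiseParams(), seed: int = 0
) -> MSPReadoutSet:
    """Raw MSP readouts realising the truth matrix under the call rules.

    With probability ``noise.flip_rate`` a reaction is drawn from the
    opposite state's readout model.  Includes a positive-control row
    per assay, an ACTB control per sample and a no-template control per
    assay.
    """
    if not truth.isin(["M", "U"]).all().all():
        raise ValueError("truth matrix must contain only 'M'/'U'")
    rng = np.random.default_rng(seed)
    controls: dict[str, msp_caller.ControlRef] = {}
    for assay in truth.index:
        controls[assay] = msp_caller.ControlRef(
            assay=assay,
            tm_celsius=float(np.round(rng.uniform(74, 86), 1)),
            amplicon_bp=int(rng.integers(80, 160)),
        )
    rows = []
    for assay in truth.index:
        ctrl = controls[assay]
        rows.append(
            {"assay": assay, "sample": "POS_CTRL",
             **_methylated_readout(rng, ctrl)}
        )
        for sample in truth.columns:
            state = truth.loc[assay, sample]
            if rng.random() < noise.flip_rate:
                state = "U" if state == "M" else "M"
            gen = _methylated_readout if state == "M" else _unmethylated_readout
            rows.append({"assay": assay, "sample": sample, **gen(rng, ctrl)})
    readouts = pd.DataFrame(rows)
    actb = pd.DataFrame(
        {
            "assay": "ACTB",
            "sample": truth.columns,
            "cq": rng.normal(28, 1, size=truth.shape[1]),
        }
    )
    ntc = pd.DataFrame(
        {"assay": truth.index, "sample": "NTC", "cq": np.inf}
    )
    return MSPReadoutSet(readouts, controls, actb, ntc)


# ---------------------------------------------------------------------------
# DAC re-expression experiment


@dataclass(frozen=True)
class DacConfig:
    n_lines: int = 8
    min_lines: int = 2          # planted genes reactivate in >= this many lines
    detection_threshold: float = 64.0
    seed: int = 0


@dataclass
class DacExperiment:
    treated: pd.DataFrame
    untreated: pd.DataFrame
    call_treated: pd.DataFrame
    call_untreated: pd.DataFrame

    @property
    def fc_matrix(self) -> pd.DataFrame:
        return np.log2(self.treated / self.untreated)


def gen_dac_experiment(
    n_probes: int,
    methylated_genes: list[str],
    cfg: DacConfig = DacConfig(),
) -> DacExperiment:
    """Paired treated/untreated expression with planted reactivation.

    Planted (methylated) genes are lowly expressed untreated and jump at
    least two-fold after treatment in at least ``cfg.min_lines`` cell
    lines, flipping their detection call from absent to present there;
    background genes carry symmetric log-normal noise.
    """
    if n_probes <= 0:
        raise ValueError("empty probe universe")
    planted = list(methylated_genes)
    if len(planted) > n_probes:
        raise ValueError("more planted genes than probes")
    rng = np.random.default_rng(cfg.seed)
    n_bg = n_probes - len(planted)
    probes = planted + [f"probe{i:05d}" for i in range(n_bg)]
    lines = [f"line{i + 1}" for i in range(cfg.n_lines)]

    untreated = np.empty((n_probes, cfg.n_lines))
    treated = np.empty_like(untreated)
    # background: comfortably detected, symmetric noise around no change
    untreated[len(planted):] = 2.0 ** rng.normal(8, 1.0, (n_bg, cfg.n_lines))
    treated[len(planted):] = untreated[len(planted):] * 2.0 ** rng.normal(
        0, 0.3, (n_bg, cfg.n_lines)
    )
    # planted: silenced untreated, strong reactivation in most lines — a
    # gene methylated across the panel reactivates wherever demethylated
    for i in range(len(planted)):
        untreated[i] = 2.0 ** rng.normal(4, 0.5, cfg.n_lines)
        lo = max(cfg.min_lines, cfg.n_lines - cfg.n_lines // 4)
        n_react = int(rng.integers(lo, cfg.n_lines + 1))
        react = rng.choice(cfg.n_lines, size=n_react, replace=False)
        fold = 2.0 ** (1.5 + np.abs(rng.normal(1.0, 0.5, cfg.n_lines)))
        quiet = 2.0 ** rng.normal(0, 0.3, cfg.n_lines)
        mult = quiet
        mult[react] = fold[react]
        treated[i] = untreated[i] * mult

    tr = pd.DataFrame(treated, index=probes, columns=lines)
    un = pd.DataFrame(untreated, index=probes, columns=lines)
    call = lambda df: df.map(
        lambda v: "present" if v >= cfg.detection_threshold else "absent"
    )
    return DacExperiment(tr, un, call(tr), call(un))


# ---------------------------------------------------------------------------
# Promoters


@dataclass
class PromoterSet:
    sequences: dict[str, str]
    tss: pd.DataFrame  # gene, chrom, tss, strand


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    bases = "ACGT"
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = bases[rng.integers(4)]
    return "".join(out)


def gen_promoters(
    genes: list[str],
    seed: int = 0,
    length: int = 600,
    families: dict[str, list[str]] | None = None,
    mutation_rate: float = 0.05,
) -> PromoterSet:
    """Random promoter sequences with optional planted sequence families.

    Genes in the same family are point-mutated copies of a common
    ancestor sequence, so k-mer clustering groups them together.  TSS
    positions are spaced along one chromosome with alternating strands.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    if families:
        for fam_genes in families.values():
            ancestor = "".join(rng.choice(bases, size=length))
            for g in fam_genes:
                seqs[g] = _mutate(ancestor, mutation_rate, rng)
    for g in genes:
        if g not in seqs:
            seqs[g] = "".join(rng.choice(bases, size=length))
    tss = pd.DataFrame(
        {
            "gene": genes,
            "chrom": "chr1",
            "tss": [10_000 + 10_000 * i for i in range(len(genes))],
            "strand": ["+" if i % 2 == 0 else "-" for i in range(len(genes))],
        }
    )
    return PromoterSet({g: seqs[g] for g in genes}, tss)


# ---------------------------------------------------------------------------
# MBD peaks and region counts


@dataclass(frozen=True)
class MbdConfig:
    n_lines: int = 8
    n_mna: int = 3
    min_lines: int = 2          # planted genes carry peaks in >= this many lines
    background_peaks: int = 30  # noise peaks per line, outside promoters
    base_mean: float = 50.0     # mean fragment count per promoter region
    mna_fold: float = 8.0       # count elevation of MNA-specific regions
    dispersion: float = 0.1
    seed: int = 0


@dataclass
class MbdData:
    peaks: dict[str, list[GenomicInterval]]
    counts: pd.DataFrame        # regions (genes) x lines
    groups: dict[str, str]      # line -> MNA / single_copy


def gen_mbd_peaks(
    promoters: PromoterSet,
    methylated_genes: list[str],
    mna_specific: list[str] | None = None,
    cfg: MbdConfig = MbdConfig(),
) -> MbdData:
    """Per-line peak sets plus a promoter-region fragment count matrix.

    Planted genes carry a peak inside the (-1,500, +1,000) promoter
    window in a designated subset of lines; MNA-specific genes carry
    them (and elevated counts) in the MNA lines only.
    """
    mna_specific = list(mna_specific or [])
    ann = promoters.tss.set_index("gene")
    missing = [g for g in methylated_genes + mna_specific if g not in ann.index]
    if missing:
        raise ValueError(f"genes without TSS annotation: {missing}")
    rng = np.random.default_rng(cfg.seed)
    lines = [f"line{i + 1}" for i in range(cfg.n_lines)]
    groups = {
        ln: ("MNA" if i < cfg.n_mna else "single_copy")
        for i, ln in enumerate(lines)
    }
    mna_lines = [ln for ln in lines if groups[ln] == "MNA"]

    def promoter_peak(gene: str) -> GenomicInterval:
        tss = int(ann.loc[gene, "tss"])
        strand = ann.loc[gene, "strand"]
        lo, hi = (tss - 1500, tss + 1000) if strand == "+" else (tss - 1000, tss + 1500)
        start = int(rng.integers(lo, hi - 150))
        return GenomicInterval(str(ann.loc[gene, "chrom"]), start, start + 150)

    peaks: dict[str, list[GenomicInterval]] = {ln: [] for ln in lines}
    for gene in methylated_genes:
        if gene in mna_specific:
            carriers = mna_lines
        else:
            n_c = int(rng.integers(cfg.min_lines, cfg.n_lines + 1))
            carriers = list(rng.choice(lines, size=n_c, replace=False))
        for ln in carriers:
            peaks[ln].append(promoter_peak(gene))
    # background peaks in intergenic space (between the spaced promoters)
    max_tss = int(promoters.tss["tss"].max())
    for ln in lines:
        for _ in range(cfg.background_peaks):
            start = int(rng.integers(0, max_tss + 20_000))
            # shift out of any promoter window (promoters sit at 10kb marks)
            if start % 10_000 < 3_000:
                start += 3_000
            peaks[ln].append(GenomicInterval("chr1", start, start + 150))

    genes = list(promoters.tss["gene"])
    r = 1.0 / cfg.dispersion
    lib = rng.uniform(0.7, 1.4, size=cfg.n_lines)
    mu = np.full((len(genes), cfg.n_lines), cfg.base_mean) * lib
    for i, g in enumerate(genes):
        if g in mna_specific:
            for j, ln in enumerate(lines):
                if groups[ln] == "MNA":
                    mu[i, j] *= cfg.mna_fold
    counts = rng.negative_binomial(r, r / (r + mu))
    return MbdData(
        peaks,
        pd.DataFrame(counts, index=genes, columns=lines),
        groups,
    )


# ---------------------------------------------------------------------------
# Survival


def gen_survival(
    clinical: pd.DataFrame,
    truth: pd.DataFrame,
    prognostic_markers: tuple[str, ...],
    hazard_multiplier: float,
    baseline_hazard: float = 1 / 1500,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times with methylation-dependent hazards.

    Each sample's hazard is ``baseline * multiplier**k`` with k its
    number of methylated prognostic markers; times are censored at the
    clinical follow-up.  Records whose clinical outcome is death of
    disease keep an event (at follow-up end if the drawn time exceeds
    it), so the generated outcomes stay consistent with the cohort.
    """
    if hazard_multiplier <= 0:
        raise ValueError("hazard multiplier must be positive")
    rng = np.random.default_rng(seed)
    markers = [m for m in prognostic_markers if m in truth.index]
    rows = []
    for r in clinical.itertuples():
        k = int((truth.loc[markers, r.sample] == "M").sum()) if markers else 0
        h = baseline_hazard * hazard_multiplier**k
        t = rng.exponential(1 / h)
        fup = float(r.followup_days)
        if t <= fup:
            time, event = t, 1
        elif r.outcome == "dod":
            time, event = fup, 1
        else:
            time, event = fup, 0
        rows.append({"sample": r.sample, "time": time, "event": event})
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# Tumor expression and qPCR


def gen_tumor_expression(
    genes: list[str],
    clinical: pd.DataFrame,
    silenced_genes: list[str],
    fold_down: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x tumor expression; silenced genes are downregulated in
    high-risk tumors (mimicking methylation-driven silencing)."""
    rng = np.random.default_rng(seed)
    samples = clinical["sample"].to_numpy()
    hr = clinical["risk_group"].isin([HR_DOD, HR_SURV]).to_numpy()
    expr = 2.0 ** rng.normal(7, 1.0, (len(genes), len(samples)))
    for i, g in enumerate(genes):
        if g in silenced_genes:
            expr[i, hr] /= fold_down
    return pd.DataFrame(expr, index=genes, columns=samples)


def gen_qpcr(
    target_genes: list[str],
    reference_genes: list[str],
    n_samples: int = 24,
    seed: int = 0,
) -> pd.DataFrame:
    """Cq table (genes x samples) with a shared per-sample offset that
    reference-gene normalization should cancel."""
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    offset = rng.normal(0, 1.0, n_samples)  # input-amount variation
    rows = {}
    for g in reference_genes:
        rows[g] = rng.normal(22, 0.3, n_samples) + offset
    for g in target_genes:
        rows[g] = rng.normal(26, 1.5, n_samples) + offset
    return pd.DataFrame(rows).T.set_axis(samples, axis=1)


# ---------------------------------------------------------------------------
# Full bundle


@dataclass
class SyntheticBundle:
    config: TruthConfig
    clinical: pd.DataFrame
    truth_calls: pd.DataFrame
    msp: MSPReadoutSet
    dac: DacExperiment
    promoters: PromoterSet
    mbd: MbdData
    survival: pd.DataFrame
    tumor_expression: pd.DataFrame
    qpcr: pd.DataFrame


def gen_bundle(
    cfg: TruthConfig = TruthConfig(),
    n_genes: int = 200,
    noise: NoiseParams = NoiseParams(),
) -> SyntheticBundle:
    """Generate every pipeline input from one seeded configuration.

    The marker genes are the planted methylated/silenced set across the
    DAC, peak and tumor-expression components, so end-to-end recovery
    can be scored against them.
    """
    markers = sorted(cfg.marker_freqs)
    clinical = gen_clinical_cohort(cfg)
    truth = gen_truth_calls(cfg, clinical)
    msp = gen_msp_readouts(truth, noise, seed=cfg.seed + 2)
    dac = gen_dac_experiment(
        n_genes, markers, DacConfig(seed=cfg.seed + 3)
    )
    genes = list(dac.treated.index)
    promoters = gen_promoters(genes, seed=cfg.seed + 4)
    mbd = gen_mbd_peaks(
        promoters,
        markers,
        sorted(cfg.mna_specific_markers),
        MbdConfig(seed=cfg.seed + 5),
    )
    surv = gen_survival(
        clinical,
        truth,
        cfg.prognostic_markers,
        cfg.hazard_multiplier,
        seed=cfg.seed + 6,
    )
    tumor = gen_tumor_expression(
        genes, clinical, markers, seed=cfg.seed + 7
    )
    qpcr = gen_qpcr(
        markers, ["HPRT1", "SDHA", "UBC"], n_samples=24, seed=cfg.seed + 8
    )
    return SyntheticBundle(
        cfg, clinical, truth, msp, dac, promoters, mbd, surv, tumor, qpcr
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write the bundle in the formats the pipeline reads (CSV/TSV,
    BED per cell line, FASTA)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    core_io.write_clinical(
        bundle.clinical[core_io.CLINICAL_COLUMNS], out / "clinical.csv"
    )
    core_io.write_matrix(bundle.truth_calls, out / "truth_calls.tsv")
    bundle.msp.readouts.to_csv(out / "msp_readouts.csv", index=False)
    pd.DataFrame(
        [
            {"assay": c.assay, "tm_celsius": c.tm_celsius, "amplicon_bp": c.amplicon_bp}
            for c in bundle.msp.controls.values()
        ]
    ).to_csv(out / "msp_controls.csv", index=False)
    core_io.write_matrix(bundle.dac.treated, out / "dac_treated.tsv")
    core_io.write_matrix(bundle.dac.untreated, out / "dac_untreated.tsv")
    core_io.write_matrix(bundle.dac.call_treated, out / "dac_calls_treated.tsv")
    core_io.write_matrix(bundle.dac.call_untreated, out / "dac_calls_untreated.tsv")
    core_io.write_fasta(bundle.promoters.sequences, out / "promoters.fasta")
    core_io.write_tss(bundle.promoters.tss, out / "tss.tsv")
    for line, peaks in bundle.mbd.peaks.items():
        core_io.write_bed(peaks, out / f"peaks_{line}.bed")
    core_io.write_matrix(bundle.mbd.counts, out / "region_counts.tsv")
    bundle.survival.to_csv(out / "survival.csv")
    core_io.write_matrix(bundle.tumor_expression, out / "tumor_expression.tsv")
    bundle.qpcr.to_csv(out / "qpcr_cq.csv")
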