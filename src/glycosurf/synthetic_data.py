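"""Synthetic cell-surface-capture data with known ground truth.

Emulates the study design end to end so every pipeline stage is testable
without the deposited data: a 30-day reprogramming time course sampled at
multi-day intervals along three doxycycline arms (DOX-high throughout;
DOX-low split off at day 8; DOX-high-to-negative withdrawn around day 14),
three technical replicates per point, an ESC reference, and proteoform
abundance trajectories drawn from five archetypes:

* ``early_down``   — fibroblast surface proteins collapsing between days 0-2;
* ``fclass_up``    — rising after DOX induction, maximal in the F-class
  (sustained DOX-high) end state, decaying after DOX withdrawal;
* ``esc_like``     — low early, high in the ESC reference and in the
  DOX-withdrawn arms as they converge to the ESC-like state;
* ``transient``    — a mid-course bump;
* ``flat``         — constant housekeeping surface proteins.

One ``fclass_up`` group is planted as the marker, elevated
``marker_effect``-fold in F-class samples over its baseline. Spectral
counts are Poisson draws against a lognormally varying per-replicate
sequencing depth (negative binomial available via ``dispersion``). The
PSM-level generator additionally embeds tryptic peptides with sequons
(including C-terminally truncated ones), sequon-less decoys, a proline
"NPS" non-sequon, deamidation modifications on sequon Asn, and planted
off-tolerance / low-confidence records — so every qualification rule is
exercised by every default fixture.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .glyco_filter import (
    CARBAMIDOMETHYL_DELTA,
    DEAMIDATION_DELTA,
    MassModel,
    find_sequons,
    peptide_mass,
)
from .io_formats import (
    DesignEntry,
    Modification,
    PSMRecord,
    TimecourseDesign,
    write_design,
    write_fasta,
    write_isoform_index,
    write_psm_table,
)
from .quantification import CountMatrix

ARCHETYPES = ("early_down", "fclass_up", "esc_like", "transient", "flat")

# arm split days: DOX-low diverges at day 8, DOX-high-to-negative at day 14
ARM_SPLIT = {"DOXL-": 8.0, "DOXH-": 14.0}
_LO = 0.06  # floor expression level, as a fraction of the archetype amplitude


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the generator.

    Defaults mirror the emulated study: 500 proteoform groups, 12 sampling
    days over a 30-day course, three technical replicates per point, an
    expected 400 spectral counts per replicate with lognormal depth
    variation (sigma 0.3), an 8-fold planted-marker elevation, and 20% of
    peptides lacking a sequon (decoys).
    """

    n_groups: int = 500
    archetype_mix: dict = field(
        default_factory=lambda: {
            "early_down": 0.3,
            "fclass_up": 0.1,
            "esc_like": 0.1,
            "transient": 0.2,
            "flat": 0.3,
        }
    )
    n_timepoints: int = 12
    total_days: int = 30
    replicates: int = 3
    mean_depth: float = 400.0
    depth_sigma: float = 0.3
    marker_effect: float = 8.0
    decoy_fraction: float = 0.2
    abundance_sigma: float = 0.5
    bad_mass_fraction: float = 0.02
    low_confidence_fraction: float = 0.02
    dispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.archetype_mix) - set(ARCHETYPES):
            raise ValueError(f"unknown archetypes in mix: {self.archetype_mix}")
        if abs(sum(self.archetype_mix.values()) - 1.0) > 1e-9:
            raise ValueError("archetype proportions must sum to 1")
        for name in ("n_groups", "n_timepoints", "replicates", "total_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mean_depth <= 0 or self.marker_effect <= 0:
            raise ValueError("mean_depth and marker_effect must be positive")
        if not 0 <= self.decoy_fraction < 1:
            raise ValueError("decoy_fraction must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Everything needed to recompute every expected intermediate."""

    archetypes: dict[str, str]
    planted_marker_id: str
    abundances: pd.DataFrame
    design: TimecourseDesign
    config: SimulationConfig
    seed: int
    # PSM-level bookkeeping (populated by simulate_psm_table)
    peptide_to_group: dict[str, str] = field(default_factory=dict)
    decoy_peptides: set[str] = field(default_factory=set)
    truncated_peptides: set[str] = field(default_factory=set)
    records_total: int = 0
    decoy_records: int = 0
    bad_mass_records: int = 0
    low_confidence_records: int = 0
    expected_qualified: int = 0


# ---------------------------------------------------------------------------
# trajectory archetypes
# ---------------------------------------------------------------------------

def _fclass_shape(day: float, condition: str) -> float:
    """0..1 activation of a DOX-driven gene along an arm."""
    if condition in ("MEF", "ESC", "iPSC"):
        return 0.0
    rise = day * day / (day * day + 64.0)
    split = ARM_SPLIT.get(condition)
    if split is not None and day > split:
        at_split = split * split / (split * split + 64.0)
        return at_split * math.exp(-(day - split) / 4.0)
    return rise


def _esc_shape(day: float, condition: str) -> float:
    """0..1 convergence toward the ESC-like expression level."""
    if condition == "ESC" or condition == "iPSC":
        return 1.0
    if condition == "MEF":
        return 0.0
    split = ARM_SPLIT.get(condition)
    if split is not None and day > split:
        return 1.0 - math.exp(-(day - split) / 5.0)
    return 0.15 * day / 30.0  # mild drift under sustained DOX


def archetype_mean(archetype: str, day: float, condition: str) -> float:
    """Expected relative abundance of an archetype at (day, condition)."""
    lo = _LO
    if archetype == "flat":
        return 1.0
    if archetype == "early_down":
        if condition in ("ESC", "iPSC"):
            return lo
        return lo + (1.0 - lo) * math.exp(-day / 1.3)
    if archetype == "fclass_up":
        return lo + (1.0 - lo) * _fclass_shape(day, condition)
    if archetype == "esc_like":
        return 0.1 + 0.9 * _esc_shape(day, condition)
    if archetype == "transient":
        if condition in ("ESC", "iPSC"):
            return lo
        return lo + (1.0 - lo) * math.exp(-(((day - 10.0) / 5.0) ** 2))
    raise ValueError(f"unknown archetype {archetype!r}")


def marker_mean(day: float, condition: str, marker_effect: float) -> float:
    """Planted-marker abundance: marker_effect-fold its floor in F-class."""
    lo = _LO
    return lo + (marker_effect - lo) * _fclass_shape(day, condition)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def make_design(config: SimulationConfig) -> TimecourseDesign:
    """Three-arm sampling design plus an ESC reference point.

    Day 0 is the starting fibroblast (MEF) point; the DOX-high arm covers
    every later day; the DOX-low and DOX-withdrawn arms are sampled from
    the first grid day after their split.
    """
    days = sorted(
        {int(round(d)) for d in np.linspace(0, config.total_days, config.n_timepoints)}
    )
    points: list[tuple[int, str]] = []
    for day in days:
        points.append((day, "MEF" if day == 0 else "DOXH"))
    for day in days:
        if day > ARM_SPLIT["DOXL-"]:
            points.append((day, "DOXL-"))
        if day > ARM_SPLIT["DOXH-"]:
            points.append((day, "DOXH-"))
    points.append((config.total_days, "ESC"))
    entries = [
        DesignEntry(f"d{day:02d}_{cond}_r{rep}", day, cond, rep)
        for day, cond in points
        for rep in range(1, config.replicates + 1)
    ]
    return TimecourseDesign(entries)


# ---------------------------------------------------------------------------
# abundances and counts
# ---------------------------------------------------------------------------

def _group_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def simulate_timecourse(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Expected abundance per group per design sample, plus the truth.

    Archetypes are assigned in proportion to ``archetype_mix``; each group
    carries one multiplicative lognormal baseline (mean 1) so the archetype
    mean is also the expected trajectory. The marker replaces one
    ``fclass_up`` group (noise-free baseline, so ``marker_effect`` is exact).
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_groups
    ids = _group_ids(n)
    counts = {a: int(round(p * n)) for a, p in config.archetype_mix.items()}
    # fix rounding drift on the largest class
    drift = n - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift
    labels = [a for a in ARCHETYPES for _ in range(counts.get(a, 0))]
    rng.shuffle(labels)
    archetypes = dict(zip(ids, labels))
    if "fclass_up" in labels:
        marker_id = ids[labels.index("fclass_up")]
    else:  # degenerate mix: plant the marker anyway
        marker_id = ids[0]
        archetypes[marker_id] = "fclass_up"
    baselines = rng.lognormal(
        mean=-config.abundance_sigma**2 / 2.0, sigma=config.abundance_sigma, size=n
    )
    design = make_design(config)
    data = np.empty((n, len(design.samples)))
    for j, entry in enumerate(design.samples):
        for i, gid in enumerate(ids):
            if gid == marker_id:
                data[i, j] = marker_mean(entry.day, entry.condition, config.marker_effect)
            else:
                data[i, j] = baselines[i] * archetype_mean(
                    archetypes[gid], entry.day, entry.condition
                )
    abundances = pd.DataFrame(data, index=ids, columns=design.sample_ids)
    truth = SyntheticTruth(
        archetypes=archetypes,
        planted_marker_id=marker_id,
        abundances=abundances,
        design=design,
        config=config,
        seed=config.seed,
    )
    return abundances, truth


def simulate_counts(
    abundances: pd.DataFrame,
    config: SimulationConfig,
    design: TimecourseDesign,
) -> CountMatrix:
    """Spectral counts: Poisson draws at lognormally varying depth.

    Each replicate run r gets a depth T_r with mean ``mean_depth``; the
    count for group g is Poisson(T_r * a_g / sum(a)). With ``dispersion``
    set, a gamma-mixed Poisson (negative binomial) is drawn instead.
    """
    rng = np.random.default_rng([config.seed, 2])
    depths = rng.lognormal(
        mean=math.log(config.mean_depth) - config.depth_sigma**2 / 2.0,
        sigma=config.depth_sigma,
        size=abundances.shape[1],
    )
    rel = abundances.to_numpy(dtype=float)
    col_sums = rel.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    lam = rel / col_sums * depths
    if config.dispersion is not None:
        shape = config.dispersion
        lam = np.where(lam > 0, rng.gamma(shape, lam / shape), 0.0)
    counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=abundances.index, columns=abundances.columns)
    return CountMatrix(values=df, design=design, state="raw",
                       reference_total=config.mean_depth)


# ---------------------------------------------------------------------------
# PSM-level fixture
# ---------------------------------------------------------------------------

_RESIDUES = "ACDEFGHILMQVWY"  # internal alphabet: no K/R/N/P/S/T surprises


def _random_core(rng, length: int) -> list[str]:
    return [_RESIDUES[i] for i in rng.integers(0, len(_RESIDUES), size=length)]


def _make_peptide(rng, kind: str) -> str:
    """One tryptic peptide: 'sequon', 'truncated', 'decoy' or 'proline'."""
    core = _random_core(rng, int(rng.integers(8, 14)))
    if kind == "sequon":
        pos = int(rng.integers(0, len(core) - 2))
        core[pos] = "N"
        core[pos + 1] = _RESIDUES[int(rng.integers(0, len(_RESIDUES)))]
        core[pos + 2] = "S" if rng.random() < 0.5 else "T"
        core.append("K" if rng.random() < 0.5 else "R")
    elif kind == "truncated":
        core.append("N")  # peptide ends at the start of a sequon
    elif kind == "proline":
        pos = int(rng.integers(0, len(core) - 2))
        core[pos], core[pos + 1], core[pos + 2] = "N", "P", "S"
        core.append("K")
    elif kind == "decoy":
        core.append("K" if rng.random() < 0.5 else "R")
    else:
        raise ValueError(kind)
    return "".join(core)


def _mods_for(peptide: str) -> tuple[Modification, ...]:
    """Fixed Cys carbamidomethylation plus deamidation on the first sequon Asn."""
    mods = [
        Modification(i + 1, CARBAMIDOMETHYL_DELTA, "carbamidomethyl")
        for i, r in enumerate(peptide)
        if r == "C"
    ]
    sequons = find_sequons(peptide)
    if sequons:
        mods.append(Modification(sequons[0].position, DEAMIDATION_DELTA, "deamidation"))
    return tuple(sorted(mods))


@dataclass
class SyntheticDataset:
    """An end-to-end fixture: PSMs, protein database, index, design, truth."""

    psms: list[PSMRecord]
    fasta: dict[str, str]
    isoform_index: dict[str, tuple[str, str]]
    design: TimecourseDesign
    counts: CountMatrix
    truth: SyntheticTruth


def simulate_psm_table(
    config: SimulationConfig, outdir=None
) -> SyntheticDataset:
    """Generate a PSM table realizing the simulated counts.

    Each group owns 1-3 tryptic peptides embedded in a generated protein
    (a subset of groups gets two isoform accessions sharing the peptides);
    ``decoy_fraction`` of peptides carry no sequon. Observed masses sit
    within ±10 ppm of theory except for a small planted spike at +50 ppm;
    confidences sit above 0.98 except for a small low-confidence spike.
    Group 0 always carries one proline "NPS" decoy and one C-terminally
    truncated sequon peptide, and at least one off-tolerance record is
    guaranteed, so every qualification rule fires on every fixture.
    """
    abundances, truth = simulate_timecourse(config)
    design = truth.design
    counts = simulate_counts(abundances, config, design)
    rng = np.random.default_rng([config.seed, 3])
    model = MassModel()

    ids = list(abundances.index)
    peptides_of: dict[str, list[str]] = {}
    seen: set[str] = set()
    for gi, gid in enumerate(ids):
        n_pep = int(rng.integers(1, 4))
        kinds = []
        for _ in range(n_pep):
            if rng.random() < config.decoy_fraction:
                kinds.append("decoy")
            elif rng.random() < 0.1:
                kinds.append("truncated")
            else:
                kinds.append("sequon")
        if gi == 0:  # guaranteed edge cases
            kinds = ["sequon", "proline", "truncated"]
        peps = []
        for kind in kinds:
            for _ in range(100):
                pep = _make_peptide(rng, kind)
                wants_sequon = kind in ("sequon", "truncated")
                if (len(find_sequons(pep)) > 0) != wants_sequon:
                    continue
                if pep not in seen:
                    break
            seen.add(pep)
            peps.append(pep)
            truth.peptide_to_group[pep] = gid
            if kind in ("decoy", "proline"):
                truth.decoy_peptides.add(pep)
            if kind == "truncated":
                truth.truncated_peptides.add(pep)
        peptides_of[gid] = peps

    fasta: dict[str, str] = {}
    isoform_index: dict[str, tuple[str, str]] = {}
    for gi, gid in enumerate(ids):
        filler = lambda: "".join(_random_core(rng, 6)) + "K"
        body = filler() + filler().join(peptides_of[gid]) + filler()
        gene = f"GENE{gi:04d}"
        acc1 = f"{gid}.1"
        fasta[acc1] = body
        isoform_index[acc1] = (gene, gid)
        if gi % 7 == 3:  # two isoforms sharing every peptide
            acc2 = f"{gid}.2"
            fasta[acc2] = body + "".join(_random_core(rng, 12))
            isoform_index[acc2] = (gene, gid)

    records: list[PSMRecord] = []
    bad_mass_candidates: list[int] = []
    for gid in ids:
        peps = peptides_of[gid]
        accs = sorted(a for a, (_, p) in isoform_index.items() if p == gid)
        row = counts.values.loc[gid]
        for sample_id, c in row.items():
            if c == 0:
                continue
            split = rng.multinomial(int(c), np.full(len(peps), 1.0 / len(peps)))
            rep = sample_id.rsplit("_r", 1)[-1]
            for pep, m in zip(peps, split):
                for _ in range(int(m)):
                    mods = _mods_for(pep)
                    theo = peptide_mass(pep, mods, model)
                    is_decoy = pep in truth.decoy_peptides
                    bad_mass = bool(rng.random() < config.bad_mass_fraction)
                    low_conf = bool(rng.random() < config.low_confidence_fraction)
                    ppm = 50.0 if bad_mass else float(rng.uniform(-10.0, 10.0))
                    conf = (
                        float(rng.uniform(0.5, 0.979))
                        if low_conf
                        else float(rng.uniform(0.981, 0.9999))
                    )
                    rec = PSMRecord(
                        peptide_sequence=pep,
                        modifications=mods,
                        observed_mass=theo * (1.0 + ppm * 1e-6),
                        confidence=conf,
                        protein_accessions=tuple(accs),
                        sample_id=sample_id,
                        replicate_id=rep,
                    )
                    if not bad_mass and not low_conf and not is_decoy:
                        bad_mass_candidates.append(len(records))
                    records.append(rec)
                    truth.records_total += 1
                    truth.decoy_records += int(is_decoy)
                    truth.bad_mass_records += int(bad_mass)
                    truth.low_confidence_records += int(low_conf)
                    truth.expected_qualified += int(
                        not is_decoy and not bad_mass and not low_conf
                    )
    if (config.bad_mass_fraction > 0 and truth.bad_mass_records == 0
            and bad_mass_candidates):
        # guarantee an off-tolerance record in every fixture
        i = bad_mass_candidates[0]
        old = records[i]
        theo = peptide_mass(old.peptide_sequence, old.modifications, model)
        records[i] = dataclasses.replace(old, observed_mass=theo * (1.0 + 50e-6))
        truth.bad_mass_records += 1
        truth.expected_qualified -= 1

    dataset = SyntheticDataset(
        psms=records,
        fasta=fasta,
        isoform_index=isoform_index,
        design=design,
        counts=counts,
        truth=truth,
    )
    if outdir is not None:
        write_dataset(dataset, outdir)
    return dataset


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_psm_table(dataset.psms, outdir / "psms.tsv")
    write_fasta(dataset.fasta, outdir / "proteins.fasta")
    write_isoform_index(dataset.isoform_index, outdir / "isoforms.tsv")
    write_design(dataset.design, outdir / "design.tsv")
    dataset.counts.to_tsv(outdir / "counts_raw.tsv")
    truth = dataset.truth
    payload = {
        "seed": truth.seed,
        "config": dataclasses.asdict(truth.config),
        "planted_marker_id": truth.planted_marker_id,
        "archetypes": truth.archetypes,
        "decoy_peptides": sorted(truth.decoy_peptides),
        "truncated_peptides": sorted(truth.truncated_peptides),
        "records_total": truth.records_total,
        "decoy_records": truth.decoy_records,
        "bad_mass_records": truth.bad_mass_records,
        "low_confidence_records": truth.low_confidence_records,
        "expected_qualified": truth.expected_qualified,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1)
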