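"""Qualification of PSMs as genuine N-glycopeptides.

After PNGase F treatment a formerly glycosylated Asn carries a +0.98402 Da
deamidation (Asn -> Asp), so a credible surface glycopeptide must

1. contain an N-glycosylation sequon N-x-[S/T] (x != P) — or, optionally, at
   least the start of one at its C terminus (the peptide may end before the
   sequon is complete);
2. carry a deamidation modification on a sequon Asn; and
3. agree with its theoretical monoisotopic mass within a ppm tolerance
   (default 20 ppm).

Every record that fails is returned with the first rule it broke, in the
fixed order sequon -> deamidation -> mass, so reports are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from pyteomics import mass as _pmass

from .io_formats import AMINO_ACIDS, Modification, PSMRecord

# chemical constants (monoisotopic Da)
DEAMIDATION_DELTA = 0.98402
CARBAMIDOMETHYL_DELTA = 57.02146
WATER_MASS = _pmass.calculate_mass(formula="H2O")

SEQUON_KINDS = ("full", "truncated_N", "truncated_Nx")


@dataclass(frozen=True)
class SequonMatch:
    """An N-glycosylation sequon occurrence, anchored at its Asn.

    ``position`` is the 1-based index of the Asn; ``kind`` is ``full`` for a
    complete N-x-[S/T] motif or ``truncated_N`` / ``truncated_Nx`` when the
    peptide C terminus cuts the motif after the Asn or after N-x.
    """

    position: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in SEQUON_KINDS:
            raise ValueError(f"unknown sequon kind {self.kind!r}")


@dataclass(frozen=True)
class MassModel:
    """Monoisotopic residue masses plus the fixed-modification deltas.

    Residue masses default to the standard amino-acid monoisotopic table;
    the deamidation delta is the exact Asn->Asp chemistry (+0.98402 Da) —
    deliberately the chemical value rather than a rounded one, since the
    difference is well below any usable ppm gate.
    """

    residue_masses: dict = field(
        default_factory=lambda: dict(_pmass.std_aa_mass)
    )
    water_mass: float = WATER_MASS
    carbamidomethyl_delta: float = CARBAMIDOMETHYL_DELTA
    deamidation_delta: float = DEAMIDATION_DELTA

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("residue masses must be positive")
        n_deam = self.residue_masses["N"] + self.deamidation_delta
        if abs(n_deam - self.residue_masses["D"]) > 1e-4:
            raise ValueError(
                "deamidated Asn mass must equal Asp mass within 1e-4 Da"
            )


@dataclass(frozen=True)
class FilterConfig:
    """Knobs for :func:`qualify_psms`.

    ``ppm_tolerance`` — maximum |observed - theoretical| mass error, in parts
    per million (default 20).
    ``require_deamidation`` — demand a deamidation modification on a sequon
    Asn (default True).
    ``allow_truncated_sequon`` — accept peptides ending in the start of a
    sequon (default True); switch off for the strict full-motif reading.
    ``deamidation_anywhere`` — accept a deamidation on any Asn rather than
    specifically a sequon Asn (default False).
    """

    ppm_tolerance: float = 20.0
    require_deamidation: bool = True
    allow_truncated_sequon: bool = True
    deamidation_anywhere: bool = False

    def __post_init__(self) -> None:
        if self.ppm_tolerance <= 0:
            raise ValueError("ppm_tolerance must be positive")


def find_sequons(peptide_sequence: str) -> list[SequonMatch]:
    """All N-glycosylation sequon matches in a peptide, overlaps included.

    A full match is N-x-[S/T] with x != P. Truncated matches are reported
    only at the C terminus: a terminal N (``truncated_N``) or terminal N-x
    with x != P (``truncated_Nx``).
    """
    bad = set(peptide_sequence) - AMINO_ACIDS
    if bad or not peptide_sequence:
        raise ValueError(f"invalid residues {sorted(bad)} in {peptide_sequence!r}")
    seq = peptide_sequence
    n = len(seq)
    matches: list[SequonMatch] = []
    for i, res in enumerate(seq):
        if res != "N":
            continue
        if i + 2 < n:
            if seq[i + 1] != "P" and seq[i + 2] in "ST":
                matches.append(SequonMatch(i + 1, "full"))
        elif i + 1 == n:
            matches.append(SequonMatch(i + 1, "truncated_N"))
        elif seq[i + 1] != "P":  # i + 2 == n
            matches.append(SequonMatch(i + 1, "truncated_Nx"))
    return matches


def is_deamidation(mod: Modification) -> bool:
    """A modification counts as deamidation by label or by mass delta.

    Labels beginning with "deamid" (any case) are accepted, as are deltas
    within 0.01 Da of the Asn->Asp shift — which admits inputs annotated
    with the commonly printed rounded value 0.986 Da.
    """
    if mod.label.lower().startswith("deamid"):
        return True
    return abs(mod.delta_mass - DEAMIDATION_DELTA) <= 0.01


def peptide_mass(
    peptide_sequence: str,
    modifications: tuple[Modification, ...] | list[Modification] = (),
    mass_model: MassModel | None = None,
) -> float:
    """Neutral monoisotopic peptide mass: residues + water + mod deltas.

    Raises if a deamidation modification is placed on a residue other than
    Asn.
    """
    model = mass_model or MassModel()
    try:
        total = sum(model.residue_masses[r] for r in peptide_sequence)
    except KeyError as exc:
        raise ValueError(f"no mass for residue {exc.args[0]!r}") from exc
    total += model.water_mass
    for mod in modifications:
        residue = peptide_sequence[mod.position - 1]
        if is_deamidation(mod) and residue != "N":
            raise ValueError(
                f"deamidation placed on {residue!r} at position {mod.position}; "
                "only Asn can carry the PNGase F signature"
            )
        total += mod.delta_mass
    return total


def ppm_error(observed_mass: float, theoretical_mass: float) -> float:
    """Relative mass deviation |obs - theo| / theo * 1e6."""
    if theoretical_mass <= 0:
        raise ValueError("theoretical_mass must be positive")
    return abs(observed_mass - theoretical_mass) / theoretical_mass * 1e6


def _sequon_positions(record: PSMRecord, config: FilterConfig) -> set[int]:
    matches = find_sequons(record.peptide_sequence)
    if not config.allow_truncated_sequon:
        matches = [m for m in matches if m.kind == "full"]
    return {m.position for m in matches}


def qualify_psms(
    records,
    mass_model: MassModel | None = None,
    config: FilterConfig | None = None,
) -> tuple[list[PSMRecord], list[tuple[PSMRecord, str]]]:
    """Split PSMs into qualified N-glycopeptides and rejects with reasons.

    A record is retained iff it has >= 1 sequon, carries a deamidation on a
    sequon Asn (when required), and its observed mass agrees with the
    theoretical mass (all modifications included) within the ppm tolerance.
    Failures never raise; each rejected record reports the first broken rule
    from {no_sequon, no_deamidation, mass_out_of_tolerance}.
    """
    model = mass_model or MassModel()
    cfg = config or FilterConfig()
    retained: list[PSMRecord] = []
    rejected: list[tuple[PSMRecord, str]] = []
    for rec in records:
        positions = _sequon_positions(rec, cfg)
        if not positions:
            rejected.append((rec, "no_sequon"))
            continue
        if cfg.require_deamidation:
            deam_positions = {
                m.position
                for m in rec.modifications
                if is_deamidation(m)
                and rec.peptide_sequence[m.position - 1] == "N"
            }
            hit = deam_positions if cfg.deamidation_anywhere else (
                deam_positions & positions
            )
            if not hit:
                rejected.append((rec, "no_deamidation"))
                continue
        theoretical = peptide_mass(rec.peptide_sequence, rec.modifications, model)
        if not math.isinf(cfg.ppm_tolerance) and (
            ppm_error(rec.observed_mass, theoretical) > cfg.ppm_tolerance
        ):
            rejected.append((rec, "mass_out_of_tolerance"))
            continue
        retained.append(rec)
    return retained, rejected
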