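"""Proteoform grouping: collapse protein isoforms sharing a gene/primary ID.

Alternate splicing yields isoforms that share stretches of sequence, so a
peptide from a shared stretch cannot be attributed to one isoform. Isoforms
are therefore quantified collectively: accessions sharing a (gene,
primary_id) pair form one proteoform group, and every peptide attaches to
every group containing a protein that includes it as an exact substring.

Peptides shared across different groups are, by default, counted in each
group; a switch excludes them instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import FormatError


@dataclass
class ProteoformGroup:
    """A set of protein isoforms quantified collectively.

    ``primary_id`` is the designated representative accession; when the
    isoform index leaves it blank, the lexicographically smallest member
    accession is used so grouping is deterministic.
    """

    primary_id: str
    gene_symbol: str = ""
    member_accessions: set[str] = field(default_factory=set)
    peptides: set[str] = field(default_factory=set)


def map_peptides(peptides, fasta_db: dict[str, str]) -> dict[str, set[str]]:
    """Map each peptide to the accessions whose sequence contains it.

    Returns every input peptide; a peptide absent from the database maps to
    an empty set (the caller can flag those via :func:`unmapped_peptides`).
    """
    if not fasta_db:
        raise ValueError("empty protein database")
    mapping: dict[str, set[str]] = {}
    for pep in peptides:
        mapping[pep] = {
            acc for acc, seq in fasta_db.items() if pep in seq
        }
    return mapping


def unmapped_peptides(peptide_map: dict[str, set[str]]) -> set[str]:
    return {pep for pep, hits in peptide_map.items() if not hits}


def build_groups(
    peptide_map: dict[str, set[str]],
    isoform_index: dict[str, tuple[str, str]],
    *,
    shared_peptides: str = "all",
) -> list[ProteoformGroup]:
    """Merge accessions into proteoform groups and attach their peptides.

    ``isoform_index`` maps accession -> (gene, primary_id). Accessions with
    the same (gene, primary_id) merge. ``shared_peptides`` controls peptides
    hitting more than one group: ``"all"`` counts them in each group (the
    collective reading), ``"drop"`` excludes them from every group. Groups
    that end up with no peptides are dropped. Output sorted by primary_id.
    """
    if shared_peptides not in ("all", "drop"):
        raise ValueError("shared_peptides must be 'all' or 'drop'")
    groups: dict[tuple[str, str], ProteoformGroup] = {}
    pep_group_keys: dict[str, set[tuple[str, str]]] = {}
    for pep, accessions in peptide_map.items():
        for acc in sorted(accessions):
            if acc not in isoform_index:
                raise FormatError(f"accession {acc!r} missing from isoform index")
            gene, primary = isoform_index[acc]
            key = (gene, primary)
            grp = groups.get(key)
            if grp is None:
                grp = groups[key] = ProteoformGroup(
                    primary_id=primary, gene_symbol=gene
                )
            grp.member_accessions.add(acc)
            pep_group_keys.setdefault(pep, set()).add(key)
    for grp in groups.values():
        if not grp.primary_id:
            grp.primary_id = min(grp.member_accessions)
    for pep, keys in pep_group_keys.items():
        if shared_peptides == "drop" and len(keys) > 1:
            continue
        for key in keys:
            groups[key].peptides.add(pep)
    return sorted(
        (g for g in groups.values() if g.peptides),
        key=lambda g: g.primary_id,
    )


def write_groups(groups, path) -> None:
    rows = [
        {
            "primary_id": g.primary_id,
            "gene": g.gene_symbol,
            "members": ";".join(sorted(g.member_accessions)),
            "peptides": ";".join(sorted(g.peptides)),
        }
        for g in groups
    ]
    pd.DataFrame(rows, columns=["primary_id", "gene", "members", "peptides"]).to_csv(
        path, sep="\t", index=False
    )


def read_groups(path) -> list[ProteoformGroup]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ProteoformGroup(
                primary_id=row.primary_id,
                gene_symbol=row.gene,
                member_accessions=set(a for a in row.members.split(";") if a),
                peptides=set(p for p in row.peptides.split(";") if p),
            )
        )
    return out
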