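"""In-silico proteolysis: trypsin, Asp-N and thermolysin, full and semi-specific.

Peptide-map sequence-variant work combines a tryptic digest with orthogonal
digests (Asp-N, thermolysin) so that every region of the protein is covered
by at least one well-behaved peptide.  This module enumerates the peptides a
search engine would consider: fully specific peptides up to a missed-cleavage
limit, and — for semi-specific searches — every sub-peptide retaining exactly
one enzyme-consistent terminus.  Protein termini always count as specific.

Coordinates are 1-based inclusive throughout, matching variant names such as
``D1E`` (residue 1 of the chain).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .chem import DEFAULT_TABLE, ResidueMassTable


@dataclass(frozen=True)
class EnzymeSpec:
    """Cleavage specificity of one protease.

    ``max_missed_cleavages=None`` means unlimited (bounded in practice by
    ``max_length``, which caps the combinatorics for frequent cutters like
    thermolysin).
    """

    name: str
    cut_side: str  # "C": cut after a member residue; "N": cut before one
    residues: frozenset[str]
    suppress_before_proline: bool = False
    max_missed_cleavages: int | None = 2
    min_length: int = 1
    max_length: int = 50

    def __post_init__(self):
        if self.cut_side not in ("C", "N"):
            raise ValueError("cut_side must be 'C' or 'N'")
        if not self.residues:
            raise ValueError("enzyme residue set must be non-empty")
        if self.min_length < 1 or self.min_length > self.max_length:
            raise ValueError("invalid peptide length bounds")


TRYPSIN = EnzymeSpec(
    "trypsin", "C", frozenset({"K", "R"}), suppress_before_proline=True,
    max_missed_cleavages=2)
ASP_N = EnzymeSpec("asp-n", "N", frozenset({"D"}), max_missed_cleavages=2)
THERMOLYSIN = EnzymeSpec(
    "thermolysin", "N", frozenset("AFILMV"),
    max_missed_cleavages=None, max_length=40)

DEFAULT_ENZYMES: dict[str, EnzymeSpec] = {
    e.name: e for e in (TRYPSIN, ASP_N, THERMOLYSIN)
}


@dataclass(frozen=True)
class ProteinRecord:
    """One protein chain with a display label (e.g. HC / LC)."""

    id: str
    chain_label: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")

    def validate_symbols(self, table: ResidueMassTable = DEFAULT_TABLE) -> None:
        for sym in self.sequence:
            if sym not in table:
                raise ValueError(
                    f"protein {self.id!r} contains unknown residue {sym!r}")


@dataclass(frozen=True)
class PeptideMatch:
    """A peptide located on its parent protein."""

    protein_id: str
    start: int  # 1-based inclusive
    end: int
    sequence: str
    enzyme: str
    n_missed: int
    specificity: str  # "full" | "semi" | "nonspecific"


def read_fasta(path: str | Path, chain_key: str = "chain") -> list[ProteinRecord]:
    """Read protein chains from FASTA.

    The chain label is taken from a ``chain=XX`` token in the description if
    present, else from an ``_HC``/``_LC`` style suffix of the id, else the id
    itself.
    """
    proteins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = rec.id
        for token in rec.description.split():
            if token.startswith(f"{chain_key}="):
                label = token.split("=", 1)[1]
                break
        else:
            if "_" in rec.id:
                label = rec.id.rsplit("_", 1)[1]
        proteins.append(ProteinRecord(rec.id, label, str(rec.seq).upper()))
    return proteins


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id} chain={p.chain_label}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i:i + 60] + "\n")


def cleavage_sites(protein: ProteinRecord, enzyme: EnzymeSpec) -> list[int]:
    """Ordered inter-residue cut positions.

    A cut position ``i`` means a cut after residue ``i`` (1-based); protein
    ends are not listed.  C-side enzymes cut after a member residue, N-side
    enzymes before one; proline suppression removes cuts immediately
    followed by P.
    """
    seq = protein.sequence
    sites = []
    for i in range(1, len(seq)):  # cut between residue i and i+1
        if enzyme.cut_side == "C":
            member = seq[i - 1] in enzyme.residues
        else:
            member = seq[i] in enzyme.residues
        if member and enzyme.suppress_before_proline and seq[i] == "P":
            member = False
        if member:
            sites.append(i)
    return sites


def classify_specificity(
    start: int, end: int, protein: ProteinRecord, enzyme: EnzymeSpec
) -> str:
    """full / semi / nonspecific status of a peptide span.

    A terminus is specific when it coincides with a cleavage site or a
    protein terminus.
    """
    if not (1 <= start <= end <= len(protein.sequence)):
        raise ValueError(
            f"span {start}-{end} outside protein {protein.id!r} "
            f"(length {len(protein.sequence)})")
    sites = set(cleavage_sites(protein, enzyme))
    n_ok = start == 1 or (start - 1) in sites
    c_ok = end == len(protein.sequence) or end in sites
    if n_ok and c_ok:
        return "full"
    if n_ok or c_ok:
        return "semi"
    return "nonspecific"


def _count_missed(sites: list[int], start: int, end: int) -> int:
    return sum(1 for s in sites if start <= s <= end - 1)


def digest(
    protein: ProteinRecord,
    enzyme: EnzymeSpec,
    specificity: str = "full",
) -> list[PeptideMatch]:
    """Enumerate digest peptides, deduplicated and ordered by (start, end).

    ``specificity="full"`` lists fully specific peptides within the enzyme's
    missed-cleavage and length limits.  ``"semi"`` additionally lists every
    sub-peptide of a fully specific peptide that retains exactly one specific
    terminus, mirroring a semi-specific search space.
    """
    if specificity not in ("full", "semi"):
        raise ValueError("specificity must be 'full' or 'semi'")
    seq = protein.sequence
    sites = cleavage_sites(protein, enzyme)
    boundaries = [0] + sites + [len(seq)]
    spans: dict[tuple[int, int], PeptideMatch] = {}

    def admit(start: int, end: int, spec: str) -> None:
        length = end - start + 1
        if not enzyme.min_length <= length <= enzyme.max_length:
            return
        key = (start, end)
        if key in spans and spans[key].specificity == "full":
            return
        spans[key] = PeptideMatch(
            protein.id, start, end, seq[start - 1:end], enzyme.name,
            _count_missed(sites, start, end), spec)

    full_spans = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, len(boundaries)):
            missed = j - i - 1
            if (enzyme.max_missed_cleavages is not None
                    and missed > enzyme.max_missed_cleavages):
                break
            start, end = boundaries[i] + 1, boundaries[j]
            if end - start + 1 > enzyme.max_length:
                break
            full_spans.append((start, end))
            admit(start, end, "full")

    if specificity == "semi":
        site_set = set(sites) | {0, len(seq)}
        for start, end in full_spans:
            for e in range(start, end):  # truncate from the C side
                admit(start, e, "full" if e in site_set else "semi")
            for s in range(start + 1, end + 1):  # truncate from the N side
                admit(s, end, "full" if (s - 1) in site_set else "semi")

    return [spans[key] for key in sorted(spans)]


def map_peptide(protein: ProteinRecord, peptide: str) -> list[tuple[int, int]]:
    """All exact (possibly overlapping) occurrences, 1-based inclusive."""
    if not peptide:
        raise ValueError("query peptide must be non-empty")
    hits = []
    pos = protein.sequence.find(peptide)
    while pos != -1:
        hits.append((pos + 1, pos + len(peptide)))
        pos = protein.sequence.find(peptide, pos + 1)
    return hits
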