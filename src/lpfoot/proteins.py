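"""Sequence-level data model for limited-proteolysis footprinting.

Residue coordinates are 1-based throughout.  "Cleavage at amino acid *i*"
always means the peptide bond C-terminal to residue *i*, so a cut pair
``(n_cut, c_cut)`` delimits the fragment spanning residues ``n_cut+1 ... c_cut``
and its length is ``c_cut - n_cut``.  ``n_cut = 0`` denotes the intact
N-terminus and ``c_cut = L`` the intact C-terminus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from Bio import SeqIO
from Bio.SeqUtils import molecular_weight

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: default average residue mass (Da) used for mass <-> length conversion
MEAN_RESIDUE_MASS = 110.0

#: default fusion-tag masses in daltons (configurable per construct)
DEFAULT_TAG_MASSES = {"GFP": 27_000.0, "myc": 1_200.0, "GST": 26_000.0}


class SequenceError(ValueError):
    """Raised for sequences containing non-standard residues."""


class RuleError(KeyError):
    """Raised for an unregistered protease-rule identifier."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with 1-based residue coordinates."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = sorted(set(self.sequence) - set(STANDARD_AA))
        if bad:
            raise SequenceError(
                f"{self.id!r}: non-standard residues {bad}; "
                f"only the 20-letter alphabet is accepted"
            )
        if not self.sequence:
            raise SequenceError(f"{self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside [1, {self.length}]")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class TerminalTag:
    """A fusion tag on one terminus (e.g. GFP, myc, GST)."""

    name: str
    side: str  # "N" or "C"
    mass: float  # daltons
    residue_count: int = 0

    def __post_init__(self) -> None:
        if self.side not in ("N", "C"):
            raise ValueError(f"tag side must be 'N' or 'C', got {self.side!r}")
        if self.mass <= 0:
            raise ValueError("tag mass must be positive")
        if self.residue_count < 0:
            raise ValueError("tag residue count must be >= 0")


@dataclass(frozen=True)
class TaggedConstruct:
    """A protein plus optional N- and C-terminal tags."""

    protein: ProteinRecord
    n_tag: TerminalTag | None = None
    c_tag: TerminalTag | None = None

    def __post_init__(self) -> None:
        if self.n_tag is not None and self.n_tag.side != "N":
            raise ValueError("n_tag must have side 'N'")
        if self.c_tag is not None and self.c_tag.side != "C":
            raise ValueError("c_tag must have side 'C'")


@dataclass(frozen=True)
class EpitopeWindow:
    """Residue interval recognized by an antibody, 1-based inclusive."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid epitope window [{self.start}, {self.end}]")


@dataclass(frozen=True)
class DomainInterval:
    name: str
    start: int
    end: int
    kind: str  # "structured" | "linker"

    def __post_init__(self) -> None:
        if self.kind not in ("structured", "linker"):
            raise ValueError(f"interval kind must be structured|linker, got {self.kind!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class HelixElement:
    domain: str
    index: int
    start: int
    end: int

    @property
    def label(self) -> str:
        return f"{self.domain} α-helix {self.index}"


@dataclass
class DomainAnnotation:
    """Non-overlapping structured/linker intervals tiling [1, length]."""

    intervals: list[DomainInterval]
    helices: list[HelixElement] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: iv.start)
        prev_end = 0
        for iv in self.intervals:
            if iv.start != prev_end + 1:
                raise ValueError(
                    f"annotation does not tile: interval {iv.name!r} starts at "
                    f"{iv.start}, expected {prev_end + 1}"
                )
            prev_end = iv.end

    @property
    def length(self) -> int:
        return self.intervals[-1].end

    def helix_at(self, position: int) -> HelixElement | None:
        for h in self.helices:
            if h.start <= position <= h.end:
                return h
        return None


# ---------------------------------------------------------------------------
# protease rules

# A rule maps (sequence, 0-based index i) -> bool: is the bond after
# residue i+1 (1-based) cleavable.  Trypsin: K or R not followed by P.
_PROTEASE_RULES: dict[str, Callable[[str, int], bool]] = {}


def register_protease_rule(name: str, predicate: Callable[[str, int], bool]) -> None:
    """Register a residue-pattern predicate under a rule identifier."""
    _PROTEASE_RULES[name] = predicate


def _trypsin(seq: str, i: int) -> bool:
    if seq[i] not in "KR":
        return False
    return i + 1 >= len(seq) or seq[i + 1] != "P"


register_protease_rule("trypsin", _trypsin)


def scan_protease_sites(protein: ProteinRecord, rule: str = "trypsin") -> list[int]:
    """Positions *i* such that the bond after residue *i* is cleavable.

    The last residue is excluded: cleavage there produces no new fragment.
    Positions are 1-based and strictly increasing.
    """
    try:
        predicate = _PROTEASE_RULES[rule]
    except KeyError:
        raise RuleError(
            f"unknown protease rule {rule!r}; registered: {sorted(_PROTEASE_RULES)}"
        ) from None
    seq = protein.sequence
    return [i + 1 for i in range(len(seq) - 1) if predicate(seq, i)]


# ---------------------------------------------------------------------------
# fragment arithmetic


def fragment_length(n_cut: int, c_cut: int) -> int:
    """Residue count of the fragment spanning ``n_cut+1 ... c_cut``."""
    if n_cut < 0:
        raise ValueError(f"n_cut must be >= 0, got {n_cut}")
    if n_cut >= c_cut:
        raise ValueError(f"need n_cut < c_cut, got {n_cut} >= {c_cut}")
    return c_cut - n_cut


#: average mass of one water molecule, Da
WATER_MASS = 18.0153


def fragment_mass(
    construct: TaggedConstruct,
    n_cut: int,
    c_cut: int,
    mode: str = "average",
    include_tags: Iterable[str] = (),
    mean_residue_mass: float = MEAN_RESIDUE_MASS,
) -> float:
    """Mass in daltons of the fragment ``n_cut+1 ... c_cut``.

    ``include_tags`` names tag sides ("N", "C") whose mass should be added; a
    tag is includable only if its terminus is retained by the fragment
    (``n_cut == 0`` for N, ``c_cut == L`` for C).
    """
    protein = construct.protein
    if not 0 <= n_cut < c_cut <= protein.length:
        raise ValueError(f"invalid cut pair ({n_cut}, {c_cut}) for length {protein.length}")
    include = set(include_tags)
    unknown = include - {"N", "C"}
    if unknown:
        raise ValueError(f"include_tags must be drawn from {{'N','C'}}, got {unknown}")

    tag_mass = 0.0
    if "N" in include:
        if construct.n_tag is None:
            raise ValueError("construct has no N tag")
        if n_cut != 0:
            raise ValueError("N tag removed by cleavage: fragment does not retain the N terminus")
        tag_mass += construct.n_tag.mass
    if "C" in include:
        if construct.c_tag is None:
            raise ValueError("construct has no C tag")
        if c_cut != protein.length:
            raise ValueError("C tag removed by cleavage: fragment does not retain the C terminus")
        tag_mass += construct.c_tag.mass

    n_res = c_cut - n_cut
    if mode == "average":
        return n_res * mean_residue_mass + tag_mass
    if mode == "exact":
        frag = protein.sequence[n_cut:c_cut]
        return float(molecular_weight(frag, seq_type="protein", monoisotopic=False)) + tag_mass
    raise ValueError(f"mode must be 'average' or 'exact', got {mode!r}")


def epitope_overlap(frag_start: int, frag_end: int, epitope: EpitopeWindow) -> int:
    """Epitope residues contained in the fragment, difference convention.

    ``max(0, min(frag_end, ep.end) - max(frag_start, ep.start))`` — the
    interval-difference count (not inclusive counting), matching how a
    fragment ending at 1314 contains 47 residues of the 1267–1379 epitope.
    """
    if frag_start > frag_end:
        raise ValueError(f"invalid fragment [{frag_start}, {frag_end}]")
    return max(0, min(frag_end, epitope.end) - max(frag_start, epitope.start))


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> ProteinRecord:
    """First record of a FASTA file; the first word of the header is the id."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return ProteinRecord(id=record.id, sequence=str(record.seq).upper())


def read_domain_table(path: str | Path) -> DomainAnnotation:
    """Tab-separated annotation with columns name, start, end, kind.

    Optional additional rows with kind ``helix`` carry helix elements and are
    expected to provide ``name`` as ``<domain>:<index>``.
    """
    intervals: list[DomainInterval] = []
    helices: list[HelixElement] = []
    text = Path(path).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, start, end, kind = line.split("\t")
        if name == "name":  # header
            continue
        if kind == "helix":
            domain, index = name.rsplit(":", 1)
            helices.append(HelixElement(domain, int(index), int(start), int(end)))
        else:
            intervals.append(DomainInterval(name, int(start), int(end), kind))
    return DomainAnnotation(intervals, helices)


def write_domain_table(annotation: DomainAnnotation, path: str | Path) -> None:
    lines = ["name\tstart\tend\tkind"]
    for iv in annotation.intervals:
        lines.append(f"{iv.name}\t{iv.start}\t{iv.end}\t{iv.kind}")
    for h in annotation.helices:
        lines.append(f"{h.domain}:{h.index}\t{h.start}\t{h.end}\thelix")
    Path(path).write_text("\n".join(lines) + "\n")


_MOTIF_TOKEN = re.compile(r"^([A-Z])(\d+)$")


def parse_motif_token(token: str) -> tuple[str, int]:
    """Parse a residue-position token such as ``K1252`` -> ('K', 1252)."""
    m = _MOTIF_TOKEN.match(token.strip())
    if not m:
        raise ValueError(f"cannot parse motif token {token!r}")
    return m.group(1), int(m.group(2))
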