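"""Anchored cleavage-site inference and differential unmasking.

A western blot reports only fragments carrying the detected feature — a
terminal tag or an internal epitope.  Each observed fragment therefore has
one *anchored* terminus whose position is known (an intact end, a retained
tag, or an assumed upstream cleavage) and one unknown terminus located by
subtracting or adding the fragment's residue length:

* C-anchored (C-tag or epitope detection): new N-terminal cut at
  ``anchor - length``;
* N-anchored (N-tag detection): new C-terminal cut at ``anchor + length``.

Inferred positions are then matched to protease motifs within a sequence
window, classified into the domain/linker annotation, and compared between
conditions: a membrane-fraction cleavage cluster with no cytosol-fraction
counterpart is an *unmasked* site — evidence of a conformational change.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .gel import mass_to_length
from .proteins import (
    DomainAnnotation,
    EpitopeWindow,
    TaggedConstruct,
    epitope_overlap,
    fragment_length,
)

#: default sequence window (residues) for candidate-motif matching
DEFAULT_MOTIF_WINDOW = 20

#: default cluster radius (residues) when merging calls across lanes
DEFAULT_MERGE_RADIUS = 5


class InfeasibleHypothesisError(ValueError):
    """An anchor hypothesis inconsistent with the observed fragment."""


@dataclass(frozen=True)
class FragmentObservation:
    """One gel band attributed to the analyzed construct."""

    gel_id: str
    lane: str
    band_id: str
    condition: str  # "cytosol" | "membrane"
    detection: str  # "n_tag" | "c_tag" | "internal_epitope"
    timepoint: float | None = None  # minutes
    estimated_mass: float | None = None  # daltons
    residue_length: int | None = None
    epitope: EpitopeWindow | None = None
    in_control: bool = False  # band also present in undigested control

    def __post_init__(self) -> None:
        if self.condition not in ("cytosol", "membrane"):
            raise ValueError(f"condition must be cytosol|membrane, got {self.condition!r}")
        if self.detection not in ("n_tag", "c_tag", "internal_epitope"):
            raise ValueError(f"unknown detection route {self.detection!r}")
        if self.estimated_mass is None and self.residue_length is None:
            raise ValueError("observation needs estimated_mass or residue_length")
        if self.detection == "internal_epitope" and self.epitope is None:
            raise ValueError("internal_epitope detection requires an epitope window")


@dataclass(frozen=True)
class AnchorHypothesis:
    """A fixed terminus: 0 = intact N, L = intact C, or an assumed cut."""

    anchored_end: str  # "N" | "C"
    anchor_position: int

    def __post_init__(self) -> None:
        if self.anchored_end not in ("N", "C"):
            raise ValueError("anchored_end must be 'N' or 'C'")
        if self.anchor_position < 0:
            raise ValueError("anchor position must be >= 0")


@dataclass(frozen=True)
class MotifMatch:
    position: int
    distance: int
    residue: str | None = None

    @property
    def label(self) -> str:
        res = self.residue or "?"
        return f"{res}{self.position}:{self.distance}"


@dataclass
class CleavageCall:
    position: int
    anchored_end: str
    anchor: int
    condition: str
    source: FragmentObservation | None = None
    candidate_motifs: list[MotifMatch] = field(default_factory=list)
    region: str | None = None
    region_kind: str | None = None
    epitope_overlap: int | None = None


def _length_of(
    observation: FragmentObservation,
    construct: TaggedConstruct | None,
    mean_residue_mass: float,
) -> int:
    if observation.residue_length is not None:
        return observation.residue_length
    retained = {"c_tag": ("C",), "n_tag": ("N",), "internal_epitope": ()}[observation.detection]
    return mass_to_length(
        observation.estimated_mass,
        construct,
        retained_tags=retained,
        mean_residue_mass=mean_residue_mass,
    )


def infer_site(
    observation: FragmentObservation,
    anchor: AnchorHypothesis,
    construct: TaggedConstruct | None = None,
    protein_length: int | None = None,
    mean_residue_mass: float = 110.0,
) -> CleavageCall:
    """Locate the unknown terminus of an observed fragment under an anchor.

    Raises :class:`InfeasibleHypothesisError` if the implied position falls
    outside ``[1, L-1]`` or, for epitope detection, if the implied fragment
    would not overlap the epitope at all.
    """
    if protein_length is None:
        if construct is None:
            raise ValueError("need protein_length or a construct")
        protein_length = construct.protein.length
    if observation.detection == "c_tag" and anchor.anchored_end != "C":
        raise ValueError("c_tag detection requires a C anchor")
    if observation.detection == "n_tag" and anchor.anchored_end != "N":
        raise ValueError("n_tag detection requires an N anchor")

    length = _length_of(observation, construct, mean_residue_mass)
    if anchor.anchored_end == "C":
        position = anchor.anchor_position - length
        frag_start, frag_end = position + 1, anchor.anchor_position
    else:
        position = anchor.anchor_position + length
        frag_start, frag_end = anchor.anchor_position + 1, position
    if not 1 <= position <= protein_length - 1:
        raise InfeasibleHypothesisError(
            f"fragment of {length} aa anchored {anchor.anchored_end}@"
            f"{anchor.anchor_position} implies cut at {position}, "
            f"outside [1, {protein_length - 1}]"
        )

    overlap = None
    if observation.detection == "internal_epitope":
        overlap = epitope_overlap(frag_start, frag_end, observation.epitope)
        if overlap == 0:
            raise InfeasibleHypothesisError(
                f"fragment {frag_start}-{frag_end} does not overlap epitope "
                f"{observation.epitope.start}-{observation.epitope.end}"
            )
    return CleavageCall(
        position=position,
        anchored_end=anchor.anchored_end,
        anchor=anchor.anchor_position,
        condition=observation.condition,
        source=observation,
        epitope_overlap=overlap,
    )


def enumerate_anchors(
    observation: FragmentObservation,
    known_c_sites: Sequence[int],
    epitope: EpitopeWindow | None = None,
    protein_length: int | None = None,
) -> list[AnchorHypothesis]:
    """Feasible C-anchors for an epitope-detected fragment.

    Candidates are the known C-side cleavage positions plus the intact
    C-terminus; a candidate is feasible iff a fragment ending there would
    overlap the epitope (difference convention).  Order follows the input
    order of ``known_c_sites``, intact terminus last.
    """
    if observation.detection != "internal_epitope":
        raise ValueError("anchor enumeration applies to internal_epitope detection")
    epitope = epitope or observation.epitope
    if protein_length is None:
        raise ValueError("protein_length is required")
    candidates = [int(s) for s in known_c_sites]
    if protein_length not in candidates:
        candidates.append(protein_length)
    anchors = [
        AnchorHypothesis("C", c)
        for c in candidates
        if epitope_overlap(1, c, epitope) > 0
    ]
    if not anchors:
        raise InfeasibleHypothesisError(
            "no candidate C-terminus yields a fragment overlapping the epitope"
        )
    return anchors


def match_motifs(
    position: int,
    motif_sites: Sequence[int],
    window: int = DEFAULT_MOTIF_WINDOW,
    residues: dict[int, str] | None = None,
) -> list[MotifMatch]:
    """Motif positions within ``window`` residues, nearest first.

    Ties in distance are reported in ascending position order.  An empty
    list means "no supporting motif".
    """
    if window < 0:
        raise ValueError(f"window must be >= 0, got {window}")
    matches = [
        MotifMatch(position=m, distance=abs(m - position),
                   residue=(residues or {}).get(m))
        for m in motif_sites
        if abs(m - position) <= window
    ]
    return sorted(matches, key=lambda m: (m.distance, m.position))


def classify_region(position: int, annotation: DomainAnnotation) -> tuple[str, str]:
    """Domain/linker interval containing a position.

    Interval boundaries are inclusive; a position shared by two intervals
    (impossible under a strict tiling, but kept as the documented tie-break)
    resolves to the upstream interval.
    """
    if not 1 <= position <= annotation.length:
        raise ValueError(f"position {position} outside [1, {annotation.length}]")
    for iv in annotation.intervals:
        if position in iv:
            return iv.name, iv.kind
    raise AssertionError("tiling invariant violated")  # pragma: no cover


def annotate_call(
    call: CleavageCall,
    annotation: DomainAnnotation | None = None,
    motif_sites: Sequence[int] | None = None,
    window: int = DEFAULT_MOTIF_WINDOW,
    motif_residues: dict[int, str] | None = None,
) -> CleavageCall:
    """Attach region classification and candidate motifs to a call."""
    if annotation is not None:
        call.region, call.region_kind = classify_region(call.position, annotation)
    if motif_sites is not None:
        call.candidate_motifs = match_motifs(
            call.position, motif_sites, window=window, residues=motif_residues
        )
    return call


@dataclass
class UnmaskedSite:
    position: int  # cluster representative (median; ties -> smaller)
    members: list[int]
    region: str | None = None
    region_kind: str | None = None


@dataclass
class UnmaskingResult:
    sites: list[UnmaskedSite]
    counts_by_kind: dict[str, int]

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def _cluster(positions: Sequence[int], radius: int) -> list[list[int]]:
    """Single-linkage clustering on the line: gap > radius starts a cluster."""
    clusters: list[list[int]] = []
    for p in sorted(positions):
        if clusters and p - clusters[-1][-1] <= radius:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


def _representative(members: Sequence[int]) -> int:
    return int(statistics.median_low(sorted(members)))


def call_unmasked_sites(
    cytosol_calls: Iterable[CleavageCall | int],
    membrane_calls: Iterable[CleavageCall | int],
    merge_radius: int = DEFAULT_MERGE_RADIUS,
    annotation: DomainAnnotation | None = None,
) -> UnmaskingResult:
    """Membrane-only cleavage clusters: the footprint of a structural shift.

    Membrane positions are clustered within ``merge_radius`` (duplicates and
    near-duplicates across lanes/timepoints collapse); a cluster is unmasked
    iff no cytosol position lies within ``merge_radius`` of it.
    """

    def pos(c: CleavageCall | int) -> int:
        return c.position if isinstance(c, CleavageCall) else int(c)

    cyt = sorted({pos(c) for c in cytosol_calls})
    mem = sorted({pos(c) for c in membrane_calls})
    sites: list[UnmaskedSite] = []
    counts: dict[str, int] = {}
    for members in _cluster(mem, merge_radius):
        if any(abs(c - m) <= merge_radius for c in cyt for m in members):
            continue
        rep = _representative(members)
        site = UnmaskedSite(position=rep, members=members)
        if annotation is not None:
            site.region, site.region_kind = classify_region(rep, annotation)
            counts[site.region_kind] = counts.get(site.region_kind, 0) + 1
        sites.append(site)
    return UnmaskingResult(sites=sites, counts_by_kind=counts)


# ---------------------------------------------------------------------------
# tables

OBSERVATION_COLUMNS = [
    "gel_id", "lane", "band_id", "condition", "timepoint_min", "detection",
    "mass_kda", "length_aa", "epitope_start", "epitope_end", "in_control",
]

REPORT_COLUMNS = [
    "calculated_site", "anchored_end", "anchor", "condition",
    "adjacent_motifs", "region", "region_kind", "unmasked",
]


def read_observation_table(path: str | Path) -> list[FragmentObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"gel_id": str, "lane": str, "band_id": str})
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation table {path} missing columns {sorted(missing)}")
    out: list[FragmentObservation] = []
    for row in df.itertuples():
        epitope = None
        if pd.notna(row.epitope_start) and pd.notna(row.epitope_end):
            epitope = EpitopeWindow(int(row.epitope_start), int(row.epitope_end))
        out.append(
            FragmentObservation(
                gel_id=row.gel_id,
                lane=row.lane,
                band_id=row.band_id,
                condition=row.condition,
                detection=row.detection,
                timepoint=float(row.timepoint_min) if pd.notna(row.timepoint_min) else None,
                estimated_mass=float(row.mass_kda) * 1e3 if pd.notna(row.mass_kda) else None,
                residue_length=int(row.length_aa) if pd.notna(row.length_aa) else None,
                epitope=epitope,
                in_control=bool(row.in_control),
            )
        )
    return out


def calls_to_frame(
    calls: Sequence[CleavageCall], unmasked_positions: set[int] | None = None
) -> pd.DataFrame:
    """Tabulate calls in the style of a cleavage-site summary table."""
    rows = []
    for c in sorted(calls, key=lambda c: c.position):
        rows.append(
            {
                "calculated_site": c.position,
                "anchored_end": c.anchored_end,
                "anchor": c.anchor,
                "condition": c.condition,
                "adjacent_motifs": ";".join(m.label for m in c.candidate_motifs),
                "region": c.region or "",
                "region_kind": c.region_kind or "",
                "unmasked": bool(unmasked_positions and c.position in unmasked_positions),
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
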