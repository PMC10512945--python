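"""Structural context for cleavage sites: accessibility and masking contacts.

A cleavage site observed only in one conformational state is expected to be
surface-accessible in that state and occluded ("masked") in the other.  This
module annotates residues of a structure model with solvent-accessible
surface area (Shrake–Rupley), an exposure class based on relative SASA, and
the spatially adjacent residues outside the local sequence window that could
provide the masking contacts.

Structures are read from PDB or mmCIF (first model, one chain, author
numbering) via biotite; a parametric ideal-helix builder provides compact
synthetic models for testing without any external structure file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .proteins import DomainAnnotation, ProteinRecord

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: van der Waals radii (Å) for heavy elements, Bondi (1964)
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}

#: residue-type maximum accessible surface areas (Å²), theoretical values of
#: Tien et al. 2013 (PLoS ONE 8:e80635); used to normalize relative SASA
MAX_SASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

DEFAULT_PROBE_RADIUS = 1.4  # Å, water
DEFAULT_SPHERE_POINTS = 960
DEFAULT_EXPOSURE_THRESHOLD = 0.25  # relative SASA
DEFAULT_CONTACT_CUTOFF = 5.0  # Å, min heavy-atom distance
DEFAULT_SEQUENCE_EXCLUSION = 4  # |Δposition| <= 4 never counts as masking


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]


@dataclass
class Residue:
    position: int  # author sequence number
    name: str  # three-letter code
    atoms: list[Atom]

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class StructureModel:
    """One chain of heavy-atom residues, author numbering."""

    residues: list[Residue]
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self._by_position = {r.position: r for r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> Residue:
        try:
            return self._by_position[position]
        except KeyError:
            raise KeyError(f"position {position} absent from structure") from None

    @property
    def positions(self) -> list[int]:
        return [r.position for r in self.residues]

    def validate_against(self, protein: ProteinRecord) -> list[str]:
        """Report numbering/identity mismatches against a sequence record."""
        issues = []
        for r in self.residues:
            if not 1 <= r.position <= protein.length:
                issues.append(f"residue {r.position} outside sequence [1, {protein.length}]")
            elif r.one_letter != "X" and protein.residue(r.position) != r.one_letter:
                issues.append(
                    f"residue {r.position}: structure {r.one_letter} vs "
                    f"sequence {protein.residue(r.position)}"
                )
        return issues


@dataclass
class NeighborContact:
    position: int
    residue_name: str
    min_distance: float  # Å, heavy atoms
    label: str | None = None  # region / helix annotation


@dataclass
class ResidueContext:
    position: int
    sasa: float  # Å²
    relative_sasa: float
    exposure: str  # "surface-exposed" | "buried"
    masking_neighbors: list[NeighborContact] = field(default_factory=list)


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def _atom_arrays(structure: StructureModel):
    coords, radii, owner = [], [], []
    for idx, res in enumerate(structure.residues):
        for atom in res.atoms:
            el = atom.element.upper()
            if el == "H":
                continue
            coords.append(atom.coord)
            radii.append(VDW_RADII.get(el, 1.70))
            owner.append(idx)
    return np.array(coords, float), np.array(radii, float), np.array(owner, int)


def compute_sasa(
    structure: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> dict[int, float]:
    """Per-residue solvent-accessible surface area in Å².

    Shrake–Rupley: each heavy atom is inflated by the probe radius and
    sampled with ``n_sphere_points`` quasi-uniform surface points; the
    accessible fraction is the fraction of points inside no other inflated
    atom.  Deterministic for a fixed point count.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    coords, radii, owner = _atom_arrays(structure)
    if coords.size == 0:
        raise ValueError("structure has no heavy atoms")
    inflated = radii + probe_radius
    unit = sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    per_residue = {r.position: 0.0 for r in structure.residues}
    max_reach = 2.0 * inflated.max()
    for i in range(len(coords)):
        pts = coords[i] + inflated[i] * unit
        # candidate occluders: atoms whose inflated spheres can reach these points
        neighbor_idx = [j for j in tree.query_ball_point(coords[i], inflated[i] + max_reach)
                        if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbor_idx:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > inflated[j] ** 2
        area = 4.0 * np.pi * inflated[i] ** 2 * accessible.mean()
        per_residue[structure.residues[owner[i]].position] += float(area)
    return per_residue


def relative_sasa(sasa: float, residue_one_letter: str) -> float:
    try:
        return sasa / MAX_SASA[residue_one_letter]
    except KeyError:
        raise ConfigurationError(
            f"no maximum-SASA reference for residue {residue_one_letter!r}"
        ) from None


def classify_exposure(
    rel_sasa: float, threshold: float = DEFAULT_EXPOSURE_THRESHOLD
) -> str:
    """Surface-exposed iff relative SASA >= threshold."""
    return "surface-exposed" if rel_sasa >= threshold else "buried"


# ---------------------------------------------------------------------------
# masking neighbors


def find_masking_neighbors(
    structure: StructureModel,
    position: int,
    distance_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    sequence_exclusion: int = DEFAULT_SEQUENCE_EXCLUSION,
    annotation: DomainAnnotation | None = None,
) -> list[NeighborContact]:
    """Residues in spatial contact but outside the local sequence window.

    Contact = minimum heavy-atom distance <= ``distance_cutoff`` and
    ``|Δposition| > sequence_exclusion`` (same-turn helix contacts are not
    "masking").  Sorted by distance.
    """
    target = structure.residue_at(position)
    tcoords = target.coords
    contacts: list[NeighborContact] = []
    for res in structure.residues:
        if abs(res.position - position) <= sequence_exclusion:
            continue
        d = float(cdist(tcoords, res.coords).min())
        if d <= distance_cutoff:
            label = None
            if annotation is not None:
                helix = annotation.helix_at(res.position)
                if helix is not None:
                    label = helix.label
                elif 1 <= res.position <= annotation.length:
                    from .inference import classify_region

                    label = classify_region(res.position, annotation)[0]
            contacts.append(
                NeighborContact(
                    position=res.position,
                    residue_name=res.name,
                    min_distance=d,
                    label=label,
                )
            )
    return sorted(contacts, key=lambda c: (c.min_distance, c.position))


def residue_context(
    structure: StructureModel,
    position: int,
    sasa_map: dict[int, float] | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
    exposure_threshold: float = DEFAULT_EXPOSURE_THRESHOLD,
    distance_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    sequence_exclusion: int = DEFAULT_SEQUENCE_EXCLUSION,
    annotation: DomainAnnotation | None = None,
) -> ResidueContext:
    """Full structural annotation for one residue position."""
    if sasa_map is None:
        sasa_map = compute_sasa(structure, probe_radius, n_sphere_points)
    res = structure.residue_at(position)
    sasa = sasa_map[position]
    rel = relative_sasa(sasa, res.one_letter)
    return ResidueContext(
        position=position,
        sasa=sasa,
        relative_sasa=rel,
        exposure=classify_exposure(rel, exposure_threshold),
        masking_neighbors=find_masking_neighbors(
            structure, position, distance_cutoff, sequence_exclusion, annotation
        ),
    )


# ---------------------------------------------------------------------------
# ideal helix builder (synthetic structure fixture)


def build_ideal_helix(
    sequence: str,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    cb_offset: float = 1.5,
) -> StructureModel:
    """Cα trace (plus pseudo-Cβ, except glycine) on an ideal helix.

    Residue *i* (1-based) sits at angle ``(i-1)*twist`` degrees and height
    ``(i-1)*rise`` Å on a cylinder of the given radius; the pseudo-Cβ is
    placed radially outward by ``cb_offset`` Å.
    """
    if not sequence:
        raise ValueError("empty sequence")
    residues = []
    for i, aa in enumerate(sequence):
        ang = np.deg2rad(i * twist)
        ca = (radius * np.cos(ang), radius * np.sin(ang), i * rise)
        atoms = [Atom("CA", "C", ca)]
        if aa != "G":
            cb = ((radius + cb_offset) * np.cos(ang), (radius + cb_offset) * np.sin(ang), i * rise)
            atoms.append(Atom("CB", "C", cb))
        residues.append(Residue(position=i + 1, name=ONE_TO_THREE.get(aa, "UNK"), atoms=atoms))
    return StructureModel(residues=residues, chain_id="A")


# ---------------------------------------------------------------------------
# structure file I/O (biotite)


def read_structure(
    path: str | Path, chain: str | None = None, model: int = 1
) -> StructureModel:
    """Read the first model of a PDB or mmCIF file into a StructureModel.

    Heavy atoms only; waters and hetero residues are dropped; ``chain``
    defaults to the first chain present.
    """
    import biotite.structure as bst
    from biotite.structure.io import pdb as bpdb
    from biotite.structure.io import pdbx as bpdbx

    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        cif = bpdbx.CIFFile.read(str(path))
        arr = bpdbx.get_structure(cif, model=model)
    else:
        pdbf = bpdb.PDBFile.read(str(path))
        arr = bpdb.get_structure(pdbf, model=model)
    arr = arr[bst.filter_amino_acids(arr) & (arr.element != "H")]
    if chain is None:
        chain = str(arr.chain_id[0])
    arr = arr[arr.chain_id == chain]
    residues: list[Residue] = []
    for res_id in np.unique(arr.res_id):
        sub = arr[arr.res_id == res_id]
        atoms = [
            Atom(name=str(a.atom_name), element=str(a.element), coord=tuple(map(float, a.coord)))
            for a in sub
        ]
        residues.append(Residue(position=int(res_id), name=str(sub.res_name[0]), atoms=atoms))
    return StructureModel(residues=residues, chain_id=chain)
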