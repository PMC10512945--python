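"""Packaged reference data for the human GBF1 footprinting study.

GBF1 is a 1859-residue Arf GEF with domains DCB, HUS, Sec7d and HDS1–3
separated by linkers.  The packaged files carry:

* ``gbf1_domains.tsv`` — a domain/linker tiling of [1, 1859] built from the
  published per-site domain assignments and the stated HDS3 span 1532–1721;
* ``gbf1_sites.tsv`` — the ten membrane-unmasked cleavage sites with their
  published candidate-motif lists (both printed spellings for site 1259),
  position labels and masking residues;
* ``gbf1_observations.tsv`` — the demo fragment series as residue lengths
  (the full-length construct masses are only reported as approximate, so
  the packaged example works in position space): three C-tag-detected
  membrane fragments and seven internal-epitope-detected membrane fragments.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .inference import (
    CleavageCall,
    FragmentObservation,
    annotate_call,
    read_observation_table,
)
from .proteins import DomainAnnotation, EpitopeWindow, parse_motif_token, read_domain_table

GBF1_LENGTH = 1859
GBF1_EPITOPE = EpitopeWindow(1267, 1379)


def _data_path(name: str) -> Path:
    return Path(resources.files("lpfoot").joinpath("data", name))


def load_gbf1_annotation() -> DomainAnnotation:
    return read_domain_table(_data_path("gbf1_domains.tsv"))


def load_gbf1_sites(spelling: str = "text") -> pd.DataFrame:
    """The ten unmasked-site records; ``spelling`` picks the motif column
    ("text" or "table") where the two printed versions differ."""
    if spelling not in ("text", "table"):
        raise ValueError("spelling must be 'text' or 'table'")
    df = pd.read_csv(_data_path("gbf1_sites.tsv"), sep="\t", comment="#")
    df["motifs"] = df[f"motifs_{spelling}"]
    return df


def gbf1_motif_positions(position: int, spelling: str = "text") -> dict[int, str]:
    """Candidate motif positions (with residue letters) for one site."""
    df = load_gbf1_sites(spelling)
    row = df[df["position"] == position]
    if row.empty:
        raise KeyError(f"no packaged site record for position {position}")
    tokens = str(row.iloc[0]["motifs"]).split(";")
    return {pos: res for res, pos in (parse_motif_token(t) for t in tokens)}


def load_gbf1_observations() -> list[FragmentObservation]:
    return read_observation_table(_data_path("gbf1_observations.tsv"))


def gbf1_demo_calls(annotation: DomainAnnotation | None = None) -> list[CleavageCall]:
    """The ten membrane cleavage calls of the demo, fully annotated.

    C-tag fragments are anchored at the intact tagged C-terminus (1859);
    internal-epitope fragments at the assumed cleavage 1314 (the favoured
    C-anchor of the two feasible ones).
    """
    annotation = annotation or load_gbf1_annotation()
    calls: list[CleavageCall] = []
    for _, row in load_gbf1_sites().iterrows():
        anchor = GBF1_LENGTH if row["series"] == "c_tag" else 1314
        motifs = {
            pos: res
            for res, pos in (parse_motif_token(t) for t in str(row["motifs"]).split(";"))
        }
        call = CleavageCall(
            position=int(row["position"]),
            anchored_end="C",
            anchor=anchor if row["series"] == "c_tag" else 1314,
            condition="membrane",
        )
        annotate_call(
            call,
            annotation=annotation,
            motif_sites=sorted(motifs),
            motif_residues=motifs,
        )
        calls.append(call)
    return calls
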