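"""End-to-end footprinting run: tables in, cleavage-site report out.

Stages: (1) load sequence/length, annotation and band observations;
(2) optionally calibrate a ladder and convert band migrations to masses;
(3) convert masses to residue lengths (subtracting retained tag masses);
(4) anchor and infer cleavage positions per detection route; (5) match
protease motifs and classify regions; (6) compare cytosol vs membrane calls
to list unmasked sites; (7) write a tab-separated report plus a JSON summary
and a log of every effective parameter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .gel import (
    estimate_mass,
    fit_standard_curve,
    ladder_from_table,
    read_band_table,
)
from .inference import (
    AnchorHypothesis,
    CleavageCall,
    FragmentObservation,
    InfeasibleHypothesisError,
    annotate_call,
    calls_to_frame,
    call_unmasked_sites,
    enumerate_anchors,
    infer_site,
    read_observation_table,
    write_report,
    DEFAULT_MERGE_RADIUS,
    DEFAULT_MOTIF_WINDOW,
)
from .proteins import (
    DEFAULT_TAG_MASSES,
    MEAN_RESIDUE_MASS,
    ProteinRecord,
    TaggedConstruct,
    TerminalTag,
    read_domain_table,
    read_fasta,
    scan_protease_sites,
)

logger = logging.getLogger("lpfoot")


@dataclass
class RunConfig:
    """Effective configuration of one footprinting run.

    Precedence when used from the CLI: flags > config file > these defaults.
    """

    observations: str | None = None
    fasta: str | None = None
    protein_length: int | None = None
    domains: str | None = None
    ladder: str | None = None
    bands: str | None = None
    structure: str | None = None
    chain: str | None = None
    out_dir: str = "lpfoot_out"

    protease_rule: str = "trypsin"
    mean_residue_mass: float = MEAN_RESIDUE_MASS
    n_tag: str | None = None  # tag name, mass from tag_masses
    c_tag: str | None = None
    tag_masses: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TAG_MASSES))
    motif_window: int = DEFAULT_MOTIF_WINDOW
    merge_radius: int = DEFAULT_MERGE_RADIUS
    anchor_preference: str = "smallest"  # smallest feasible C-anchor
    sasa_probe_radius: float = 1.4
    sasa_points: int = 960
    exposure_threshold: float = 0.25
    neighbor_cutoff: float = 5.0
    sequence_exclusion: int = 4
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "mean_residue_mass": self.mean_residue_mass,
            "sasa_probe_radius": self.sasa_probe_radius,
            "sasa_points": self.sasa_points,
            "exposure_threshold": self.exposure_threshold,
            "neighbor_cutoff": self.neighbor_cutoff,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.motif_window < 0 or self.merge_radius < 0 or self.sequence_exclusion < 0:
            raise ValueError("window/radius/exclusion parameters must be >= 0")
        if self.fasta is None and self.protein_length is None:
            raise ValueError("need a FASTA sequence or an explicit protein_length")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _build_construct(config: RunConfig, protein: ProteinRecord | None) -> TaggedConstruct | None:
    if protein is None:
        return None
    n_tag = c_tag = None
    if config.n_tag:
        n_tag = TerminalTag(config.n_tag, "N", config.tag_masses[config.n_tag])
    if config.c_tag:
        c_tag = TerminalTag(config.c_tag, "C", config.tag_masses[config.c_tag])
    return TaggedConstruct(protein=protein, n_tag=n_tag, c_tag=c_tag)


def _observation_lengths(
    observations: list[FragmentObservation],
    config: RunConfig,
) -> None:
    """Attach estimated masses from a ladder + bands pair, if configured."""
    if config.ladder is None or config.bands is None:
        return
    ladder = ladder_from_table(read_band_table(config.ladder))
    curve = fit_standard_curve(ladder)
    logger.info(
        "standard curve: slope=%.5f intercept=%.5f r2=%s n=%d",
        curve.slope, curve.intercept, curve.r_squared, curve.n_bands,
    )
    bands = read_band_table(config.bands)
    by_key = {
        (r.gel_id, r.lane, r.band_id): float(r.migration) for r in bands.itertuples()
    }
    for obs in observations:
        key = (obs.gel_id, obs.lane, obs.band_id)
        if key in by_key:
            est = estimate_mass(curve, by_key[key])
            object.__setattr__(obs, "estimated_mass", est.mass)
            object.__setattr__(obs, "residue_length", None)


def infer_all_calls(
    observations: list[FragmentObservation],
    construct: TaggedConstruct | None,
    protein_length: int,
    config: RunConfig,
) -> list[CleavageCall]:
    """Anchor and infer every usable observation.

    Terminal-tag fragments anchor at the intact tagged terminus.  Epitope
    fragments enumerate C-anchors over the cleavage positions already
    inferred from C-tag fragments in the same condition (plus the intact
    C-terminus) and keep the preferred feasible one (default: smallest).
    """
    usable = [o for o in observations if not o.in_control]
    calls: list[CleavageCall] = []
    known_c: dict[str, list[int]] = {"cytosol": [], "membrane": []}

    for obs in usable:  # terminal-tag routes first: they feed the anchor sets
        if obs.detection == "c_tag":
            anchor = AnchorHypothesis("C", protein_length)
        elif obs.detection == "n_tag":
            anchor = AnchorHypothesis("N", 0)
        else:
            continue
        call = infer_site(obs, anchor, construct, protein_length, config.mean_residue_mass)
        calls.append(call)
        if obs.detection == "c_tag":
            known_c[obs.condition].append(call.position)

    for obs in usable:
        if obs.detection != "internal_epitope":
            continue
        anchors = enumerate_anchors(
            obs, sorted(set(known_c[obs.condition])), protein_length=protein_length
        )
        feasible: list[CleavageCall] = []
        for anchor in sorted(anchors, key=lambda a: a.anchor_position):
            try:
                feasible.append(
                    infer_site(obs, anchor, construct, protein_length,
                               config.mean_residue_mass)
                )
            except InfeasibleHypothesisError:
                continue
        if not feasible:
            raise InfeasibleHypothesisError(
                f"band {obs.gel_id}/{obs.lane}/{obs.band_id}: no feasible anchor"
            )
        if config.anchor_preference != "smallest":
            raise ValueError(f"unknown anchor preference {config.anchor_preference!r}")
        calls.append(feasible[0])
    return calls


@dataclass
class RunResult:
    calls: list[CleavageCall]
    report: pd.DataFrame
    summary: dict


def run_footprint(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write report, summary and log."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("lpfoot %s", __version__)
        logger.info("effective config: %s", json.dumps(dataclasses.asdict(config), sort_keys=True))

        protein = read_fasta(config.fasta) if config.fasta else None
        protein_length = protein.length if protein else config.protein_length
        construct = _build_construct(config, protein)
        annotation = read_domain_table(config.domains) if config.domains else None
        if annotation is not None and annotation.length != protein_length:
            raise ValueError(
                f"annotation tiles [1, {annotation.length}] but protein length is "
                f"{protein_length}"
            )
        observations = read_observation_table(config.observations)
        n_control = sum(o.in_control for o in observations)
        if n_control:
            logger.info("excluding %d control-lane bands", n_control)
        _observation_lengths(observations, config)

        motif_sites = scan_protease_sites(protein, config.protease_rule) if protein else None
        motif_residues = (
            {p: protein.residue(p) for p in motif_sites} if protein else None
        )

        calls = infer_all_calls(observations, construct, protein_length, config)
        for call in calls:
            annotate_call(
                call,
                annotation=annotation,
                motif_sites=motif_sites,
                window=config.motif_window,
                motif_residues=motif_residues,
            )

        cytosol = [c for c in calls if c.condition == "cytosol"]
        membrane = [c for c in calls if c.condition == "membrane"]
        unmasking = call_unmasked_sites(
            cytosol, membrane, merge_radius=config.merge_radius, annotation=annotation
        )
        unmasked_pos = {m for s in unmasking.sites for m in s.members}
        report = calls_to_frame(calls, unmasked_positions=unmasked_pos)

        structure_rows = None
        if config.structure:
            structure_rows = _structure_annotations(config, unmasking, annotation)

        summary = {
            "tool_version": __version__,
            "n_observations": len(observations) - n_control,
            "n_calls": len(calls),
            "unmasked_sites": [s.position for s in unmasking.sites],
            "n_unmasked": unmasking.n_sites,
            "n_unmasked_by_kind": unmasking.counts_by_kind,
        }
        write_report(report, out / "calls.tsv")
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        if structure_rows is not None:
            structure_rows.to_csv(out / "structure_context.tsv", sep="\t",
                                  index=False, lineterminator="\n")
        logger.info("wrote %d calls, %d unmasked sites", len(calls), unmasking.n_sites)
        return RunResult(calls=calls, report=report, summary=summary)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _structure_annotations(config: RunConfig, unmasking, annotation) -> pd.DataFrame:
    from .structure import compute_sasa, read_structure, residue_context

    model = read_structure(config.structure, chain=config.chain)
    sasa_map = compute_sasa(model, config.sasa_probe_radius, config.sasa_points)
    rows = []
    for site in unmasking.sites:
        try:
            ctx = residue_context(
                model, site.position, sasa_map=sasa_map,
                exposure_threshold=config.exposure_threshold,
                distance_cutoff=config.neighbor_cutoff,
                sequence_exclusion=config.sequence_exclusion,
                annotation=annotation,
            )
        except KeyError:
            logger.warning("site %d absent from structure model", site.position)
            continue
        rows.append(
            {
                "position": ctx.position,
                "sasa_A2": round(ctx.sasa, 2),
                "relative_sasa": round(ctx.relative_sasa, 4),
                "exposure": ctx.exposure,
                "masking_neighbors": ";".join(
                    f"{c.residue_name}{c.position}:{c.min_distance:.2f}"
                    + (f"({c.label})" if c.label else "")
                    for c in ctx.masking_neighbors
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["position", "sasa_A2", "relative_sasa", "exposure", "masking_neighbors"]
    )
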