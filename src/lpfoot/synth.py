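"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is a pure function of its parameters and seed (one
``numpy.random.Generator`` threaded explicitly, no global state), so each
stage of the footprinting pipeline — digestion, gel migration, calibration,
anchored inference, differential unmasking, image quantification — has a
recovery test against planted truth.

The default scenario mirrors the scale of a limited-proteolysis experiment
on a large multidomain protein: ~1859 residues, an internal epitope near
[1267, 1379], a C-terminal tag, and 10 membrane-only cleavage sites placed
on real tryptic motifs of the generated sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coloc import ChannelImage
from .gel import LadderBand, StandardCurve, fit_standard_curve, predict_migration
from .proteins import (
    MEAN_RESIDUE_MASS,
    STANDARD_AA,
    DomainAnnotation,
    DomainInterval,
    EpitopeWindow,
    ProteinRecord,
    TaggedConstruct,
    TerminalTag,
    scan_protease_sites,
)
from .inference import FragmentObservation


class ConfigurationError(ValueError):
    pass


#: a typical prestained-ladder mass series, kDa
DEFAULT_LADDER_KDA = (250.0, 150.0, 100.0, 75.0, 50.0, 37.0, 25.0, 20.0, 15.0, 10.0)


def make_protein(
    length: int,
    kr_density: float = 0.1,
    n_domains: int = 4,
    seed: int | np.random.Generator = 0,
    forbid_kp: bool = False,
    id: str = "synthetic",
) -> tuple[ProteinRecord, DomainAnnotation]:
    """Random sequence with controlled K/R density plus a tiling annotation.

    ``n_domains`` structured blocks alternate with linkers; with
    ``forbid_kp`` no K/R is immediately followed by P, so every K/R except a
    terminal one is a tryptic motif.
    """
    if length < 50:
        raise ConfigurationError(f"length must be >= 50, got {length}")
    if not 0 < kr_density < 0.3:
        raise ConfigurationError(f"kr_density must be in (0, 0.3), got {kr_density}")
    if n_domains < 1 or 2 * n_domains + 1 > length // 10:
        raise ConfigurationError(f"infeasible n_domains {n_domains} for length {length}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    others = [a for a in STANDARD_AA if a not in "KR"]
    seq: list[str] = []
    for _ in range(length):
        if rng.random() < kr_density:
            seq.append("K" if rng.random() < 0.5 else "R")
        else:
            seq.append(str(rng.choice(others)))
    if forbid_kp:
        safe = [a for a in others if a != "P"]
        for i in range(1, length):
            if seq[i] == "P" and seq[i - 1] in "KR":
                seq[i] = str(rng.choice(safe))
    protein = ProteinRecord(id=id, sequence="".join(seq))

    # alternate linker/structured blocks: L D L D ... D L
    n_blocks = 2 * n_domains + 1
    bounds = np.linspace(0, length, n_blocks + 1).astype(int)
    intervals = []
    for b in range(n_blocks):
        start, end = bounds[b] + 1, bounds[b + 1]
        if start > end:
            continue
        if b % 2 == 1:
            intervals.append(DomainInterval(f"D{(b // 2) + 1}", start, end, "structured"))
        else:
            intervals.append(DomainInterval(f"linker{b // 2}", start, end, "linker"))
    return protein, DomainAnnotation(intervals)


def plant_sites(
    protein: ProteinRecord,
    target_positions: Sequence[int],
    rule: str = "trypsin",
) -> list[int]:
    """Snap target positions to the nearest actual protease motif."""
    motifs = np.array(scan_protease_sites(protein, rule))
    if motifs.size == 0:
        raise ConfigurationError("sequence has no protease motifs")
    planted = sorted({int(motifs[np.abs(motifs - t).argmin()]) for t in target_positions})
    return planted


def simulate_digestion(
    construct: TaggedConstruct,
    planted_sites: Sequence[int],
    detection: str,
    condition_map: Mapping[int, str],
    epitope: EpitopeWindow | None = None,
    timepoints: Sequence[float] = (15.0, 30.0),
    mean_residue_mass: float = MEAN_RESIDUE_MASS,
    gel_id: str = "gel1",
) -> list[FragmentObservation]:
    """Band lists for a partial limited-proteolysis digest, both fractions.

    ``condition_map`` labels each planted site ``"both"`` (always exposed)
    or ``"membrane"`` (unmasked only on membranes); cytosol lanes carry only
    the always-exposed cuts.  For terminal-tag detection every cut yields
    one tagged fragment; for epitope detection the fragments between
    consecutive cuts that overlap the epitope are emitted.  Timepoint lanes
    are replicates (no kinetics).
    """
    protein = construct.protein
    L = protein.length
    motifs = set(scan_protease_sites(protein))
    for s in planted_sites:
        if s not in motifs:
            raise ConfigurationError(f"planted site {s} is not a protease motif")
        if s not in condition_map:
            raise ConfigurationError(f"planted site {s} missing from condition_map")
    if detection == "internal_epitope" and epitope is None:
        raise ConfigurationError("internal_epitope detection requires an epitope")

    def fragments_for(sites: Sequence[int]) -> list[tuple[int, float]]:
        """(residue_length, mass Da) per observable band."""
        out = []
        if detection == "c_tag":
            if construct.c_tag is None:
                raise ConfigurationError("c_tag detection requires a C tag")
            for s in sites:
                n = L - s
                out.append((n, n * mean_residue_mass + construct.c_tag.mass))
        elif detection == "n_tag":
            if construct.n_tag is None:
                raise ConfigurationError("n_tag detection requires an N tag")
            for s in sites:
                out.append((s, s * mean_residue_mass + construct.n_tag.mass))
        elif detection == "internal_epitope":
            bounds = [0] + sorted(sites) + [L]
            for a, b in zip(bounds[:-1], bounds[1:]):
                overlap = max(0, min(b, epitope.end) - max(a + 1, epitope.start))
                if overlap > 0:
                    out.append((b - a, (b - a) * mean_residue_mass))
        else:
            raise ConfigurationError(f"unknown detection route {detection!r}")
        return out

    always = sorted(s for s in planted_sites if condition_map[s] == "both")
    observations: list[FragmentObservation] = []
    for condition, sites in (("cytosol", always), ("membrane", sorted(planted_sites))):
        for t in timepoints:
            lane = f"{condition[0].upper()}{int(t)}"
            for k, (n_res, mass) in enumerate(fragments_for(sites)):
                observations.append(
                    FragmentObservation(
                        gel_id=gel_id,
                        lane=lane,
                        band_id=f"{lane}b{k}",
                        condition=condition,
                        detection=detection,
                        timepoint=t,
                        estimated_mass=mass,
                        residue_length=n_res,
                        epitope=epitope,
                    )
                )
    return observations


def simulate_gel(
    fragments: Sequence[FragmentObservation],
    true_curve: StandardCurve,
    migration_noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    ladder_kda: Sequence[float] = DEFAULT_LADDER_KDA,
    gel_id: str = "gel1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Migrate fragments on a log-linear gel; return (ladder, bands) tables.

    ``migration_noise_sd`` is a relative SD: each band's migration is
    multiplied by ``1 + N(0, sd)``.  The ladder is emitted noise-free.
    """
    if migration_noise_sd < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ladder_rows = [
        {"gel_id": gel_id, "lane": "ladder", "band_id": f"L{i}",
         "migration": predict_migration(true_curve, kda * 1e3), "mass_kda": kda}
        for i, kda in enumerate(ladder_kda)
    ]
    band_rows = []
    for obs in fragments:
        mig = predict_migration(true_curve, obs.estimated_mass)
        mig *= 1.0 + rng.normal(0.0, migration_noise_sd) if migration_noise_sd else 1.0
        band_rows.append(
            {"gel_id": obs.gel_id, "lane": obs.lane, "band_id": obs.band_id,
             "migration": mig, "mass_kda": np.nan}
        )
    return pd.DataFrame(ladder_rows), pd.DataFrame(band_rows)


def make_microscopy_pair(
    shape: tuple[int, int] = (128, 128),
    cell_geometry: tuple[tuple[float, float], float] = ((64.0, 64.0), 45.0),
    golgi_geometry: tuple[tuple[float, float], float] = ((52.0, 70.0), 10.0),
    planted_fraction: float = 25.0,
    snr: float = 50.0,
    seed: int | np.random.Generator = 0,
) -> tuple[ChannelImage, ChannelImage, dict]:
    """Two-channel field with a planted Golgi fraction of the green signal.

    The red channel is flat background noise plus a bright disc (the
    organelle), bright enough to clear the mean + 5 SD threshold at the
    stated SNR.  Green intensity inside the cell disc is split so that
    ``planted_fraction`` percent of the in-cell total lies inside the
    organelle disc.  Returns (green, red, ground_truth).
    """
    if not 0.0 <= planted_fraction <= 100.0:
        raise ConfigurationError(f"planted_fraction must be in [0, 100], got {planted_fraction}")
    (ccy, ccx), cr = cell_geometry
    (gcy, gcx), gr = golgi_geometry
    if np.hypot(gcy - ccy, gcx - ccx) + gr > cr:
        raise ConfigurationError("golgi region must lie inside the cell region")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    cell = (yy - ccy) ** 2 + (xx - ccx) ** 2 <= cr**2
    golgi = (yy - gcy) ** 2 + (xx - gcx) ** 2 <= gr**2

    bg_mean, bg_sd = 100.0, 5.0
    red = rng.normal(bg_mean, bg_sd, shape)
    red[golgi] += snr * bg_sd  # clears mean + 5 SD by construction for snr >> 5
    red = np.clip(red, 0, None)

    n_golgi = int(golgi.sum())
    n_rest = int((cell & ~golgi).sum())
    base = 1000.0
    f = planted_fraction / 100.0
    green = np.zeros(shape)
    if f >= 1.0:
        g_golgi, g_rest = base, 0.0
    elif f <= 0.0:
        g_golgi, g_rest = 0.0, base
    else:
        g_rest = base
        g_golgi = f / (1.0 - f) * g_rest * n_rest / n_golgi
    green[cell] = g_rest
    green[golgi] = g_golgi
    # low-amplitude shot-like noise, zero outside the cell so the mean
    # threshold cleanly separates cell from background
    green[cell] += rng.normal(0.0, base / snr, size=n_golgi + n_rest)
    green = np.clip(green, 0, None)

    truth = {
        "planted_fraction": planted_fraction,
        "cell_pixels": int(cell.sum()),
        "golgi_pixels": n_golgi,
    }
    return (
        ChannelImage(green, channel="green"),
        ChannelImage(red, channel="red"),
        truth,
    )


# ---------------------------------------------------------------------------
# a complete scenario, paper-scale by default


@dataclass
class SyntheticScenario:
    seed: int
    protein: ProteinRecord
    annotation: DomainAnnotation
    construct: TaggedConstruct
    epitope: EpitopeWindow
    planted_sites: list[int]
    condition_map: dict[int, str]
    true_curve: StandardCurve
    migration_noise_sd: float
    observations: list[FragmentObservation] = field(default_factory=list)


#: target positions for the default 10 membrane-only sites (snapped to the
#: nearest motif of the generated sequence)
DEFAULT_SITE_TARGETS = (178, 342, 469, 605, 642, 687, 878, 1259, 1314, 1369)


def make_scenario(
    seed: int = 0,
    length: int = 1859,
    kr_density: float = 0.1,
    n_domains: int = 6,
    epitope: tuple[int, int] = (1267, 1379),
    site_targets: Sequence[int] = DEFAULT_SITE_TARGETS,
    migration_noise_sd: float = 0.0,
    detections: Sequence[str] = ("c_tag", "internal_epitope"),
) -> SyntheticScenario:
    """Default study-scale scenario: tagged ~1859-residue protein, internal
    epitope, 10 membrane-only cleavage sites, log-linear gel."""
    rng = np.random.default_rng(seed)
    protein, annotation = make_protein(
        length, kr_density, n_domains, seed=rng, forbid_kp=True, id=f"synth{seed}"
    )
    construct = TaggedConstruct(
        protein=protein,
        n_tag=TerminalTag("GFP", "N", 27_000.0, 239),
        c_tag=TerminalTag("myc", "C", 1_200.0, 11),
    )
    ep = EpitopeWindow(*epitope)
    planted = plant_sites(protein, site_targets)
    condition_map = {s: "membrane" for s in planted}
    curve = StandardCurve(
        slope=-0.02, intercept=2.6, r_squared=None, n_bands=0,
        migration_min=0.0, migration_max=100.0,
    )
    scenario = SyntheticScenario(
        seed=seed,
        protein=protein,
        annotation=annotation,
        construct=construct,
        epitope=ep,
        planted_sites=planted,
        condition_map=condition_map,
        true_curve=curve,
        migration_noise_sd=migration_noise_sd,
    )
    for det in detections:
        scenario.observations.extend(
            simulate_digestion(
                construct, planted, det, condition_map,
                epitope=ep if det == "internal_epitope" else None,
                gel_id=f"gel_{det}",
            )
        )
    return scenario


def write_scenario(scenario: SyntheticScenario, out_dir: str | Path) -> None:
    """Write a scenario directory: FASTA, annotation, tables, ground truth."""
    from .gel import write_band_table
    from .proteins import write_domain_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = f">{scenario.protein.id}\n"
    seq = scenario.protein.sequence
    fasta += "\n".join(seq[i: i + 60] for i in range(0, len(seq), 60)) + "\n"
    (out / "protein.fasta").write_text(fasta)
    write_domain_table(scenario.annotation, out / "domains.tsv")

    rows = []
    for obs in scenario.observations:
        rows.append(
            {
                "gel_id": obs.gel_id, "lane": obs.lane, "band_id": obs.band_id,
                "condition": obs.condition, "timepoint_min": obs.timepoint,
                "detection": obs.detection,
                "mass_kda": obs.estimated_mass / 1e3 if obs.estimated_mass else np.nan,
                "length_aa": obs.residue_length,
                "epitope_start": obs.epitope.start if obs.epitope else np.nan,
                "epitope_end": obs.epitope.end if obs.epitope else np.nan,
                "in_control": obs.in_control,
            }
        )
    pd.DataFrame(rows).to_csv(out / "observations.tsv", sep="\t", index=False,
                              lineterminator="\n")

    ladder, bands = simulate_gel(
        scenario.observations, scenario.true_curve,
        scenario.migration_noise_sd, seed=scenario.seed,
    )
    write_band_table(ladder, out / "ladder.tsv")
    write_band_table(bands, out / "bands.tsv")

    truth = {
        "seed": scenario.seed,
        "protein_length": scenario.protein.length,
        "epitope": [scenario.epitope.start, scenario.epitope.end],
        "planted_sites": scenario.planted_sites,
        "condition_map": {str(k): v for k, v in scenario.condition_map.items()},
        "true_curve": {"slope": scenario.true_curve.slope,
                       "intercept": scenario.true_curve.intercept},
        "migration_noise_sd": scenario.migration_noise_sd,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
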