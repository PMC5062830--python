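"""Study-shaped synthetic data generation.

Emulates the sampling design of a 17-population Neotropical tree survey:
per-population sample sizes totalling 257 individuals grouped into three
regions, two sequence partitions with distinct substitution models
(a ~1.7 kb chloroplast concatenation under HKY+Gamma and a 518 bp
nuclear ITS fragment under TIM1+Gamma), fictional but regionally
clustered coordinates on a 0.5-degree grid, and toy suitability rasters
for three time slices (LGM, mid-Holocene, present) with a controllable
range-shift displacement.

Sequences are generated by simulating one genealogy per partition under
a chosen demographic scenario and evolving alignments on it, so the
"truth" (generating hypothesis and every parameter) is known and
recorded alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .coalescent import SampleConfig, simulate_genealogy
from .diversity import PopulationMap
from .io import (
    write_coordinates,
    write_fasta,
    write_popmap,
    write_provenance,
    write_raster,
)
from .scenarios import InvalidParameterError, Scenario, build_hypothesis_scenario
from .seqevo import Alignment, SubstitutionModel, build_substitution_model, evolve_alignment
from .spatial import GeoPoint, SuitabilityRaster

#: Population codes, sample sizes and region tags of the emulated survey
#: (three regions, 257 individuals total).
STUDY_POPULATIONS: tuple[tuple[str, int, str], ...] = (
    ("CCM", 20, "North-Northeast"),
    ("CRA", 9, "North-Northeast"),
    ("POF", 27, "North-Northeast"),
    ("SEC", 4, "North-Northeast"),
    ("ALT", 32, "Central-West"),
    ("ARA", 13, "Central-West"),
    ("BOD", 10, "Central-West"),
    ("GSV", 3, "Central-West"),
    ("LUZ", 30, "Central-West"),
    ("MIM", 13, "Central-West"),
    ("POT", 2, "Central-West"),
    ("PNA", 4, "Central-West"),
    ("CAP", 23, "Southeast"),
    ("PNI", 21, "Southeast"),
    ("SAB", 6, "Southeast"),
    ("SCA", 21, "Southeast"),
    ("SUM", 19, "Southeast"),
)

# Fictional regional anchors (lat, lon) on a 0.5-degree grid; populations
# are scattered around their region's anchor.
_REGION_ANCHORS = {
    "North-Northeast": (-7.25, -40.25),
    "Central-West": (-15.25, -49.75),
    "Southeast": (-20.75, -44.75),
}


@dataclass(frozen=True)
class PartitionSpec:
    """Sequence-simulation settings for one partition."""

    name: str
    length: int
    model: SubstitutionModel
    mu: float
    size_multiplier: float = 1.0


@dataclass(frozen=True)
class StudyTemplate:
    """Everything needed to generate one synthetic study dataset."""

    populations: tuple[tuple[str, int, str], ...] = STUDY_POPULATIONS
    partitions: tuple[PartitionSpec, ...] = ()
    scenario: Scenario | None = None
    master_seed: int = 0

    def sample_config(self) -> SampleConfig:
        return SampleConfig(
            sizes={i + 1: n for i, (_, n, _) in enumerate(self.populations)}
        )

    def population_map(self) -> dict[str, str]:
        return {code: region for code, _, region in self.populations}


def default_template(
    scenario_name: str = "PPPH",
    master_seed: int = 0,
    n_demes: int | None = None,
) -> StudyTemplate:
    """The study-shaped default: 17 populations, cpDNA + ITS partitions.

    Mutation rates are calibrated so pooled diversities fall in the
    study-like range (pi of order 1e-3) under the generating scenario;
    they are explicit template parameters, not estimates.
    """
    if n_demes is None:
        n_demes = len(STUDY_POPULATIONS)
    scenario = build_hypothesis_scenario(scenario_name, n_demes=n_demes)
    cp_model = build_substitution_model("HKY", kappa=1.5, alpha=0.0170, ncat=4)
    its_model = build_substitution_model(
        "TIM1", rates=(1.0, 2.0, 1.0, 2.0), alpha=0.010, ncat=4
    )
    partitions = (
        PartitionSpec(name="cpDNA", length=1742, model=cp_model, mu=5e-7),
        PartitionSpec(name="ITS", length=518, model=its_model, mu=1.2e-6),
    )
    return StudyTemplate(
        partitions=partitions, scenario=scenario, master_seed=master_seed
    )


def population_coordinates(
    populations: tuple[tuple[str, int, str], ...] = STUDY_POPULATIONS,
    seed: int = 0,
    cellsize: float = 0.5,
) -> dict[str, GeoPoint]:
    """Fictional, regionally clustered coordinates on grid-cell centers."""
    rng = np.random.default_rng(seed)
    coords: dict[str, GeoPoint] = {}
    taken: set[tuple[float, float]] = set()
    for code, _, region in populations:
        base_lat, base_lon = _REGION_ANCHORS[region]
        while True:
            dlat = cellsize * rng.integers(-6, 7)
            dlon = cellsize * rng.integers(-6, 7)
            lat, lon = base_lat + dlat, base_lon + dlon
            if (lat, lon) not in taken:
                taken.add((lat, lon))
                break
        coords[code] = GeoPoint(lat=lat, lon=lon)
    return coords


@dataclass
class DatasetBundle:
    """An in-memory synthetic dataset with its generating truth."""

    alignments: dict[str, Alignment]
    popmap: PopulationMap
    coordinates: dict[str, GeoPoint]
    truth: dict


def generate_dataset(template: StudyTemplate) -> DatasetBundle:
    """Simulate one dataset (one genealogy per partition) from a template."""
    if template.scenario is None or not template.partitions:
        raise InvalidParameterError("template needs a scenario and partitions")
    scenario = template.scenario
    if scenario.n_demes < len(template.populations):
        raise InvalidParameterError(
            "scenario has fewer demes than template populations"
        )
    root = np.random.SeedSequence(template.master_seed)
    streams = root.spawn(len(template.partitions))
    samples = template.sample_config()

    codes = [code for code, _, _ in template.populations]
    labels: list[str] = []
    assignments: dict[str, str] = {}
    for i, (code, n, _) in enumerate(template.populations):
        for j in range(n):
            label = f"{code}_{j + 1:03d}"
            labels.append(label)
            assignments[label] = code

    alignments: dict[str, Alignment] = {}
    for part, ss in zip(template.partitions, streams):
        seeds = ss.generate_state(2, dtype=np.uint32)
        g = simulate_genealogy(
            scenario, samples, seed=int(seeds[0]),
            size_multiplier=part.size_multiplier,
        )
        rng = np.random.default_rng(int(seeds[1]))
        aln = evolve_alignment(
            g, part.model, part.length, part.mu, rng, partition=part.name
        )
        # leaves are emitted in deme order, matching the label order above
        alignments[part.name] = Alignment(
            data=aln.data, labels=tuple(labels), partition=part.name
        )

    regions = {code: region for code, _, region in template.populations}
    popmap = PopulationMap(assignments=assignments, regions=regions)
    coords = population_coordinates(template.populations,
                                    seed=template.master_seed)
    truth = {
        "generating_scenario": scenario.to_dict(),
        "master_seed": template.master_seed,
        "partitions": [
            {
                "name": p.name, "length": p.length, "mu": p.mu,
                "family": p.model.family, "alpha": p.model.alpha,
                "ncat": p.model.ncat,
                "size_multiplier": p.size_multiplier,
            }
            for p in template.partitions
        ],
        "populations": [
            {"code": c, "n": n, "region": r}
            for c, n, r in template.populations
        ],
    }
    return DatasetBundle(
        alignments=alignments, popmap=popmap, coordinates=coords, truth=truth
    )


def write_bundle(bundle: DatasetBundle, outdir: str | Path) -> list[Path]:
    """Write a dataset bundle to disk; returns the files written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, aln in bundle.alignments.items():
        p = outdir / f"{name}.fasta"
        write_fasta(aln, p)
        written.append(p)
    p = outdir / "popmap.tsv"
    write_popmap(bundle.popmap, p)
    written.append(p)
    p = outdir / "coordinates.tsv"
    write_coordinates(bundle.coordinates, p)
    written.append(p)
    p = outdir / "truth.yaml"
    write_provenance(bundle.truth, p)
    written.append(p)
    return written


def generate_suitability_rasters(
    seed: int = 0,
    nrows: int = 40,
    ncols: int = 60,
    xll: float = -60.0,
    yll: float = -25.0,
    cellsize: float = 0.5,
    shift_cells: int = 6,
    smooth_sigma: float = 3.0,
) -> dict[str, SuitabilityRaster]:
    """Toy suitability rasters for 21 ka, 6 ka and present.

    A smooth random field modulated by an interior Gaussian envelope
    (so the suitable area never touches the grid edge) is displaced
    eastward by ``shift_cells`` columns at the LGM and half that at the
    mid-Holocene, emulating a postglacial westward range shift of
    ``shift_cells * cellsize`` degrees of longitude.
    """
    rng = np.random.default_rng(seed)
    noise = gaussian_filter(rng.random((nrows, ncols)), smooth_sigma)
    lo, hi = noise.min(), noise.max()
    noise = (noise - lo) / (hi - lo) if hi > lo else np.zeros_like(noise)
    r = np.arange(nrows)[:, None]
    c = np.arange(ncols)[None, :]
    envelope = np.exp(
        -(((r - nrows / 2) / (nrows / 5.0)) ** 2
          + ((c - ncols / 2) / (ncols / 6.0)) ** 2)
    )
    present = np.clip(envelope * (0.4 + 0.6 * noise), 0.0, 1.0)
    slices = {
        "present": present,
        "6ka": np.roll(present, shift_cells // 2, axis=1),
        "21ka": np.roll(present, shift_cells, axis=1),
    }
    return {
        tag: SuitabilityRaster(
            values=vals, xll=xll, yll=yll, cellsize=cellsize, time_slice=tag
        )
        for tag, vals in slices.items()
    }


def write_rasters(
    rasters: dict[str, SuitabilityRaster], outdir: str | Path
) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for tag, raster in rasters.items():
        p = outdir / f"suitability_{tag}.asc"
        write_raster(raster, p)
        written.append(p)
    return written
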