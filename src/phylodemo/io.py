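"""Readers and writers for the pipeline's plain-text formats.

FASTA alignments (via Biopython), two-column population maps, population
coordinate tables, ESRI-ASCII-style suitability rasters, and YAML
scenario/run configuration.  Sequences are uppercased and U is
normalized to T on input.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .diversity import PopulationMap
from .scenarios import InvalidParameterError, Scenario
from .seqevo import Alignment
from .spatial import GeoPoint, SuitabilityRaster


class FormatError(ValueError):
    """Malformed input file."""


def read_fasta(path: str | Path, partition: str = "") -> Alignment:
    """Read an alignment from FASTA; rejects ragged or duplicate records."""
    path = Path(path)
    labels: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in labels:
            raise FormatError(f"duplicate sequence label {rec.id!r} in {path}")
        labels.append(rec.id)
        seqs.append(str(rec.seq))
    if not labels:
        raise FormatError(f"no sequences found in {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        bad = [l for l, s in zip(labels, seqs) if len(s) != len(seqs[0])][0]
        raise FormatError(f"ragged alignment in {path}: offending label {bad!r}")
    return Alignment.from_strings(labels, seqs, partition=partition or path.stem)


def write_fasta(aln: Alignment, path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for i, label in enumerate(aln.labels):
            fh.write(f">{label}\n")
            s = aln.sequence(i)
            for j in range(0, len(s), width):
                fh.write(s[j:j + width] + "\n")


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a tab-separated label -> population table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two tab-separated columns")
    labels = df.iloc[:, 0]
    if labels.duplicated().any():
        dups = labels[labels.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate labels {dups}")
    return PopulationMap(assignments=dict(zip(labels, df.iloc[:, 1])))


def write_popmap(pops: PopulationMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for label, pop in pops.assignments.items():
            fh.write(f"{label}\t{pop}\n")


def read_coordinates(path: str | Path) -> dict[str, GeoPoint]:
    """Read a population/lat/lon tab-separated table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"population", "lat", "lon"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    return {
        str(r.population): GeoPoint(lat=float(r.lat), lon=float(r.lon))
        for r in df.itertuples()
    }


def write_coordinates(coords: dict[str, GeoPoint], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("population\tlat\tlon\n")
        for pop, pt in coords.items():
            fh.write(f"{pop}\t{pt.lat}\t{pt.lon}\n")


def read_raster(path: str | Path, time_slice: str = "") -> SuitabilityRaster:
    """Read an ESRI-ASCII-style grid."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: missing raster header field {key}")
    values = np.array(rows)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FormatError(
            f"{path}: grid is {values.shape}, header says "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return SuitabilityRaster(
        values=values,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
        time_slice=time_slice or path.stem,
    )


def write_raster(raster: SuitabilityRaster, path: str | Path) -> None:
    nrows, ncols = raster.shape
    with Path(path).open("w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.xll}\n")
        fh.write(f"yllcorner {raster.yll}\n")
        fh.write(f"cellsize {raster.cellsize}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        for row in raster.values:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_scenario(path: str | Path) -> Scenario:
    return Scenario.from_yaml(Path(path).read_text())


def write_scenario(scenario: Scenario, path: str | Path) -> None:
    Path(path).write_text(scenario.to_yaml())


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_provenance(config: dict, path: str | Path) -> None:
    """Write a YAML sidecar embedding the config and its hash."""
    data = dict(config)
    data["config_hash"] = config_hash(config)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_run_config(path: str | Path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise FormatError(f"{path}: run configuration must be a mapping")
    return data
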