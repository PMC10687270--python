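"""Read and write genome definition files (YAML or TSV).

TSV columns: chrom, length, centromere (empty allowed), is_autosome.
YAML shape::

    name: CPOR
    chromosomes:
      - {id: "1", length: 230000000, centromere: 45000000, is_autosome: true}
      - {id: "X",  length: 160000000, is_autosome: false}
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Union

import yaml

from .model import ChromosomeDef, GenomeDef

_TRUE = {"1", "true", "yes", "t", "y"}
_FALSE = {"0", "false", "no", "f", "n"}


def _parse_bool(value: str, context: str) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"{context}: cannot interpret {value!r} as boolean")


def read_genome_def(path: Union[str, Path], name: Optional[str] = None) -> GenomeDef:
    """Load a genome definition, dispatching on file extension."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        return _read_yaml(path, name)
    return _read_tsv(path, name)


def _read_yaml(path: Path, name: Optional[str]) -> GenomeDef:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "chromosomes" not in data:
        raise ValueError(f"{path}: expected a mapping with a 'chromosomes' list")
    chroms = []
    for entry in data["chromosomes"]:
        chroms.append(
            ChromosomeDef(
                id=str(entry["id"]),
                length=int(entry["length"]),
                centromere=None
                if entry.get("centromere") is None
                else int(entry["centromere"]),
                is_autosome=bool(entry.get("is_autosome", True)),
            )
        )
    return GenomeDef(name=name or str(data.get("name", path.stem)), chromosomes=tuple(chroms))


def _read_tsv(path: Path, name: Optional[str]) -> GenomeDef:
    chroms = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"chrom", "length", "centromere", "is_autosome"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: TSV needs columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            cen = row["centromere"].strip()
            chroms.append(
                ChromosomeDef(
                    id=row["chrom"].strip(),
                    length=int(row["length"]),
                    centromere=int(cen) if cen else None,
                    is_autosome=_parse_bool(row["is_autosome"], f"{path} line {i}"),
                )
            )
    return GenomeDef(name=name or path.stem, chromosomes=tuple(chroms))


def write_genome_def(genome: GenomeDef, path: Union[str, Path]) -> None:
    """Write a genome definition, YAML or TSV by extension."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = {
            "name": genome.name,
            "chromosomes": [
                {
                    "id": c.id,
                    "length": c.length,
                    "centromere": c.centromere,
                    "is_autosome": c.is_autosome,
                }
                for c in genome.chromosomes
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "length", "centromere", "is_autosome"])
        for c in genome.chromosomes:
            writer.writerow(
                [
                    c.id,
                    c.length,
                    "" if c.centromere is None else c.centromere,
                    "true" if c.is_autosome else "false",
                ]
            )
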