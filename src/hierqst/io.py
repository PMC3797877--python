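"""Readers and writers for the delimited-text data formats.

All tables are comma-separated UTF-8. Phenotype files use ``NA`` as the
missing-value marker; genotype files follow the GenAlEx codominant
convention of two integer allele columns per locus with 0 marking a
missing copy. Validation is total: malformed input raises
:class:`~hierqst.design.ValidationError` naming the offending row and
column rather than silently coercing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import (
    LABEL_COLUMNS,
    GenotypeTable,
    PhenotypeTable,
    PopulationInfo,
    StudyDesign,
    ValidationError,
)

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes",
    "write_genotypes",
    "read_design",
    "write_design",
    "write_results",
]

log = logging.getLogger("hierqst")

MISSING = "NA"


def read_design(path: str | Path) -> StudyDesign:
    """Read population metadata (id, region, elevation, coordinates)."""
    df = pd.read_csv(path, dtype={"population": str, "region": str})
    required = {"population", "region", "elevation"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"design file missing column(s) {sorted(missing)!r}")
    pops = [
        PopulationInfo(
            population=str(r.population),
            region=str(r.region),
            elevation=float(r.elevation),
            longitude=float(getattr(r, "longitude", np.nan)),
            latitude=float(getattr(r, "latitude", np.nan)),
        )
        for r in df.itertuples(index=False)
    ]
    return StudyDesign(tuple(pops))


def write_design(design: StudyDesign, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "population": p.population,
                "region": p.region,
                "elevation": p.elevation,
                "longitude": p.longitude,
                "latitude": p.latitude,
            }
            for p in design.populations
        ]
    ).to_csv(path, index=False)


def read_phenotypes(path: str | Path, design: StudyDesign) -> PhenotypeTable:
    """Read a per-plant phenotype CSV and validate it against ``design``.

    The header must name every label column of :data:`LABEL_COLUMNS`; all
    remaining columns are treated as traits. A non-numeric trait cell other
    than the ``NA`` marker is a parse error naming the row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        dtype={"plant_id": str, "region": str, "population": str, "family": str, "treatment": str},
        na_values=[MISSING],
        keep_default_na=False,
    )
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: malformed header, missing column(s) {missing!r}")
    traits = [c for c in df.columns if c not in LABEL_COLUMNS]
    for col in traits + ["initial_diameter"]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise ValidationError(
                f"{path.name}: non-numeric value {df.loc[row, col]!r} "
                f"in column {col!r}, data row {row + 1}"
            )
        df[col] = converted
    if len(df) == 0:
        log.warning("%s: file contains a valid header but no data rows", path.name)
    table = PhenotypeTable(df, design, traits)
    log.info("read %d phenotype rows, %d trait(s) from %s", len(df), len(traits), path.name)
    return table


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, na_rep=MISSING)


def read_genotypes(path: str | Path, design: StudyDesign) -> GenotypeTable:
    """Read a GenAlEx-style codominant genotype CSV.

    Expects ``individual_id``, ``region``, ``population`` followed by an
    even number of integer allele columns, two per locus, named
    ``<locus>_1`` / ``<locus>_2``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"individual_id": str, "region": str, "population": str})
    label_cols = ["individual_id", "region", "population"]
    missing = [c for c in label_cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: malformed header, missing column(s) {missing!r}")
    allele_cols = [c for c in df.columns if c not in label_cols]
    if len(allele_cols) % 2 != 0:
        raise ValidationError(
            f"{path.name}: odd number of allele columns ({len(allele_cols)}); "
            "codominant data needs two per locus"
        )
    loci = []
    for i in range(0, len(allele_cols), 2):
        c1, c2 = allele_cols[i], allele_cols[i + 1]
        if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
            raise ValidationError(
                f"{path.name}: allele columns must come in <locus>_1/<locus>_2 pairs, "
                f"got {c1!r}, {c2!r}"
            )
        loci.append(c1[:-2])
    for c in allele_cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise ValidationError(
                f"{path.name}: non-integer allele code {df.loc[row, c]!r} "
                f"in column {c!r}, data row {row + 1}"
            )
        if (converted < 0).any():
            raise ValidationError(f"{path.name}: negative allele code in column {c!r}")
        if (converted != converted.astype(np.int64)).any():
            raise ValidationError(f"{path.name}: fractional allele code in column {c!r}")
        df[c] = converted.astype(np.int64)
    table = GenotypeTable(df, design, loci)
    for locus in loci:
        miss = float((df[f"{locus}_1"] == 0).mean()) if len(df) else 0.0
        log.info("locus %s: missingness %.1f%%", locus, 100 * miss)
    return table


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame],
    path: str | Path,
    *,
    config: Mapping | None = None,
    seed: int | None = None,
    inputs: Mapping[str, str | Path] | None = None,
) -> None:
    """Write one CSV per result table plus a machine-readable run manifest.

    The manifest records the configuration, the seed and SHA-256 checksums of
    the input files (when given); it carries no timestamps, so a rerun with
    identical inputs and seed is byte-identical.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False, na_rep=MISSING, float_format="%.10g")
    manifest = {
        "config": dict(config) if config else {},
        "seed": seed,
        "inputs": {k: _sha256(Path(v)) for k, v in (inputs or {}).items()},
        "tables": sorted(tables),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
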