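"""Readers and writers for the tabular formats of the pipeline.

Everything is TSV.  Result tables are written with a leading commented
header (``# key<TAB>value`` lines) recording the tool version and the
parameters that produced them; all readers skip ``#`` lines, so results
round-trip through the same readers.  Allelic count tables are accepted in
two dialects: the package's native schema and the standard ASE read-counter
header (contig/position/refAllele/altAllele/refCount/altCount), mapped on
read.  Positions are 1-based, as in VCF and pileup.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .design import DESIGN_COLUMNS, LIBRARY_KEY, validate_design

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """File does not match the expected column layout."""


class JoinError(ValueError):
    """Sample keys in a table do not join to the design."""


class ValidationError(ValueError):
    """Row-level values violate the schema."""


#: ASE read-counter style header -> native names
COUNT_DIALECT = {
    "contig": "chrom",
    "position": "pos",
    "variantID": "snp_id",
    "refAllele": "ref_allele",
    "altAllele": "alt_allele",
    "refCount": "ref_count",
    "altCount": "alt_count",
}

COUNT_COLUMNS = [
    "chrom", "pos", "ref_allele", "alt_allele", "snp_id",
    "individual", "cell_type", "treatment", "plate", "ref_count", "alt_count",
]


@dataclass
class Config:
    """Pipeline thresholds and generator settings."""

    min_coverage: int = 5
    fdr_level: float = 0.10
    min_conditions_per_celltype: int = 5
    min_resid_df: int = 5
    seed: int = 0
    out_dir: str = "results"
    generator: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValidationError("fdr_level must lie in (0, 1)")
        if self.min_coverage < 0:
            raise ValidationError("min_coverage must be >= 0")
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")


def load_config(path: str | Path) -> Config:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return Config(**data)
    except TypeError as exc:
        raise FormatError(f"unrecognized config keys in {path}: {exc}") from exc


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """TSV with a commented provenance header (version + parameters)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# casekit\t{__version__}\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}\t{value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    return pd.read_csv(path, sep="\t", comment="#")


def _count_header_offset(path: Path) -> int:
    """1-based line number of the header row (after leading comments)."""
    offset = 1
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                offset += 1
            else:
                break
    return offset


def read_design(path: str | Path) -> pd.DataFrame:
    design = read_table(path)
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns and c != "is_control"]
    if missing:
        raise FormatError(f"design table missing columns: {missing}")
    if "is_control" not in design.columns:
        design["is_control"] = design["treatment"] == design["vehicle"]
    validate_design(design)
    return design


def write_design(design: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    write_table(design, path, meta)


def read_allelic_counts(path: str | Path, design: pd.DataFrame) -> pd.DataFrame:
    """Validated allelic count records joined to the design.

    Rows failing validation raise :class:`ValidationError` naming the file
    line; sample keys absent from the design raise :class:`JoinError`
    listing the orphan keys.
    """
    path = Path(path)
    raw = read_table(path).rename(columns=COUNT_DIALECT)
    required = [c for c in COUNT_COLUMNS if c != "snp_id"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {missing}")
    if "snp_id" not in raw.columns:
        raw["snp_id"] = raw["chrom"].astype(str) + ":" + raw["pos"].astype(str)
    header_line = _count_header_offset(path)
    line_no = raw.index.to_numpy() + header_line + 1

    problems = []
    for col in ("ref_count", "alt_count"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals % 1 != 0)
        for i in raw.index[bad]:
            problems.append(f"line {line_no[i]}: {col}={raw.loc[i, col]!r} is not a non-negative integer")
    pos = pd.to_numeric(raw["pos"], errors="coerce")
    for i in raw.index[pos.isna() | (pos < 1)]:
        problems.append(f"line {line_no[i]}: pos={raw.loc[i, 'pos']!r} must be a 1-based position")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    raw["ref_count"] = raw["ref_count"].astype(int)
    raw["alt_count"] = raw["alt_count"].astype(int)
    raw["pos"] = raw["pos"].astype(int)

    key_cols = [k for k in LIBRARY_KEY]
    dup = raw.duplicated(subset=["snp_id"] + key_cols)
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate (snp_id, individual, cell_type, treatment, plate) keys "
            f"at lines {[int(line_no[i]) for i in raw.index[dup]][:10]}"
        )

    design_keys = design[key_cols + ["vehicle"]].drop_duplicates()
    merged = raw.drop(columns=["vehicle"], errors="ignore").merge(
        design_keys, on=key_cols, how="left", validate="many_to_one"
    )
    orphans = merged["vehicle"].isna()
    if orphans.any():
        keys = (
            merged.loc[orphans, key_cols]
            .drop_duplicates()
            .apply(lambda r: ":".join(map(str, r)), axis=1)
            .tolist()
        )
        raise JoinError(f"{path}: sample keys not in design: {keys[:20]}")
    cols = COUNT_COLUMNS[:9] + ["vehicle"] + COUNT_COLUMNS[9:]
    cols = ["chrom", "pos", "ref_allele", "alt_allele", "snp_id",
            "individual", "cell_type", "treatment", "vehicle", "plate",
            "ref_count", "alt_count"]
    return merged[cols]


def write_allelic_counts(counts: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    write_table(counts.drop(columns=["vehicle"], errors="ignore"), path, meta)


PSI_DIALECT = {
    "cluster": "cluster_id",
    "intron": "intron_id",
    "deltapsi": "delta_psi",
    "deltaPsi": "delta_psi",
    "dPSI": "delta_psi",
    "significant": "cluster_significant",
}

PSI_COLUMNS = ["condition", "cluster_id", "intron_id", "delta_psi", "cluster_significant"]


def read_delta_psi(path: str | Path) -> pd.DataFrame:
    """Per-intron delta-PSI records; |delta_psi| must not exceed 1."""
    path = Path(path)
    raw = read_table(path).rename(columns=PSI_DIALECT)
    missing = [c for c in PSI_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {missing}")
    if len(raw) == 0:
        log.warning("%s: empty delta-PSI table", path)
        return raw[PSI_COLUMNS]
    header_line = _count_header_offset(path)
    vals = pd.to_numeric(raw["delta_psi"], errors="coerce")
    bad = vals.isna() | (vals.abs() > 1)
    if bad.any():
        lines = [int(i) + header_line + 1 for i in raw.index[bad]]
        raise ValidationError(
            f"{path}: delta_psi outside [-1, 1] at lines {lines[:20]}"
        )
    raw["delta_psi"] = vals
    raw["cluster_significant"] = raw["cluster_significant"].astype(bool)
    return raw[PSI_COLUMNS]


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Gene sets: either one identifier per line (set named by file stem) or
    a two-column TSV of (set_label, gene)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    if not rows:
        return {}
    if all(len(r) == 1 for r in rows):
        return {path.stem: {r[0] for r in rows}}
    sets: dict[str, set[str]] = {}
    for r in rows:
        sets.setdefault(r[0], set()).add(r[1])
    return sets


def write_provenance(path: str | Path, config: Config, inputs: dict[str, str | Path] | None = None,
                     extra: dict | None = None) -> None:
    """Machine-readable provenance record (JSON): version, seed, thresholds,
    input hashes."""
    record = {
        "tool": "casekit",
        "version": __version__,
        "config": asdict(config),
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in (inputs or {}).items()
        },
    }
    if extra:
        record.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
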