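"""File formats, configuration and shared plumbing for the coexpression pipeline.

All tabular formats are plain TSV; gene sets are GMT; genomic intervals are
BED3+ with 0-based half-open coordinates.  Floats are written with 17
significant digits so that write -> read round-trips are exact for float64.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("hybcoex")

FLOAT_FMT = "%.17g"

POPULATIONS = ("F2", "HZ", "pure_dom", "pure_mus")
PURE_POPULATIONS = ("pure_dom", "pure_mus")
HYBRID_POPULATIONS = ("F2", "HZ")
SCALE_TAGS = ("raw", "background_corrected", "normalized", "log2", "batch_adjusted")
MOTILITY_TRAITS = ("VCL", "VAP", "VSL", "ALH", "BCF")


class FormatError(ValueError):
    """A file violates the declared on-disk format."""


class ShapeError(ValueError):
    """Two paired inputs disagree in shape or identifiers."""


class ConfigError(ValueError):
    """Invalid configuration value or unknown key."""


def setup_logging(level: str = "INFO") -> None:
    """Route pipeline logs to stderr with timestamps."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    log.handlers[:] = [handler]
    log.setLevel(getattr(logging, level.upper()))


def derive_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the single root seed.

    Stable across platforms and Python hash randomization (uses blake2b,
    not ``hash``).  Result is always < 2**31.
    """
    digest = hashlib.blake2b(f"{root_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


def stage_rng(root_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(root_seed, stage))


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Probes x samples real-valued intensity or log2-intensity matrix."""

    data: pd.DataFrame  # index = probe ids, columns = sample ids
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate probe id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.scale_tag)

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [p for p in probe_ids if p not in self.data.index]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(probe_ids)], self.scale_tag)

    def with_values(self, values: np.ndarray, scale_tag: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            pd.DataFrame(values, index=self.data.index, columns=self.data.columns),
            scale_tag,
        )


def _read_tsv_matrix(path: str | Path, id_name: str = "probe_id") -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate {id_name} {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str), dtype=float)
    for col in df.columns:
        # parse via float() for exact 17-digit round trips (pandas' fast
        # to_numeric path loses the last couple of digits)
        try:
            out[col] = np.array([float(x) for x in df[col]], dtype=float)
        except (ValueError, TypeError):
            for i, x in enumerate(df[col]):
                try:
                    float(x)
                except (ValueError, TypeError):
                    raise FormatError(
                        f"{path}: non-numeric value {x!r} at row "
                        f"{df.index[i]!r}, column {col!r}"
                    ) from None
            raise
    return out


def read_expression_tsv(
    path: str | Path,
    background_path: str | Path | None = None,
    scale_tag: str = "raw",
) -> ExpressionMatrix | tuple[ExpressionMatrix, ExpressionMatrix]:
    """Read a probes x samples TSV (first column probe ids, header sample ids).

    With ``background_path`` a paired background-intensity matrix is read and
    checked for identical shape and identifiers.
    """
    fg = ExpressionMatrix(_read_tsv_matrix(path), scale_tag)
    if background_path is None:
        return fg
    bg = ExpressionMatrix(_read_tsv_matrix(background_path), scale_tag)
    if fg.probe_ids != bg.probe_ids or fg.sample_ids != bg.sample_ids:
        raise ShapeError(
            f"background matrix {background_path} does not match foreground "
            f"{path} in shape/identifiers"
        )
    return fg, bg


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Probe annotation and sample tables
# ---------------------------------------------------------------------------

PROBE_ANNOT_COLUMNS = ["probe_id", "gene_id", "is_negative_control"]


def validate_probe_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    for col in PROBE_ANNOT_COLUMNS:
        if col not in annot.columns:
            raise FormatError(f"probe annotation missing column {col!r}")
    if annot["probe_id"].duplicated().any():
        dup = annot.loc[annot["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"duplicate probe annotation for {dup!r}")
    neg = annot["is_negative_control"].astype(bool)
    genes = annot["gene_id"].fillna("").astype(str)
    if (neg & (genes != "")).any():
        raise FormatError("negative-control probes must have empty gene_id")
    out = annot.copy()
    out["gene_id"] = genes
    out["is_negative_control"] = neg
    return out.reset_index(drop=True)


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str})
    df["gene_id"] = df["gene_id"].fillna("")
    return validate_probe_annotation(df)


def write_probe_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    validate_probe_annotation(annot).to_csv(path, sep="\t", index=False)


SAMPLE_COLUMNS = [
    "sample_id", "population", "batch", "body_weight", "testis_weight", "sperm_count",
]


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in SAMPLE_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"sample table missing column {col!r}")
    if table["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in sample table")
    bad_pop = set(table["population"]) - set(POPULATIONS)
    if bad_pop:
        raise FormatError(f"unknown population labels {sorted(bad_pop)}")
    if (table["body_weight"] <= 0).any():
        raise FormatError("body_weight must be > 0")
    if (table["testis_weight"] < 0).any() or (table["sperm_count"] < 0).any():
        raise FormatError("testis_weight and sperm_count must be >= 0")
    return table.reset_index(drop=True)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str})
    return validate_sample_table(df)


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_sample_table(table).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def relative_testis_weight(table: pd.DataFrame) -> pd.Series:
    """testis weight / body weight (g/g), indexed by sample_id."""
    rtw = table["testis_weight"] / table["body_weight"]
    rtw.index = table["sample_id"]
    return rtw


# ---------------------------------------------------------------------------
# Gene sets (GMT) and genomic intervals (BED)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> gene ids...

    Duplicate gene ids within a line are dropped (first occurrence kept);
    duplicate set names are an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = list(dict.fromkeys(g for g in fields[2:] if g))
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"interval {self.chrom}:{self.start}-{self.end} has start >= end"
            )


def read_bed(path: str | Path) -> list[Interval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            name = fields[3] if len(fields) > 3 else ""
            intervals.append(Interval(chrom, start, end, name))
    return intervals


def write_bed(intervals: Sequence[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name:
                fields.append(iv.name)
            fh.write("\t".join(fields) + "\n")


@dataclass
class AnnotationBundle:
    """Gene positions, named interval sets, and named gene sets by category.

    ``gene_positions`` maps gene_id -> Interval (0-based half-open);
    ``gene_sets`` maps category in {term, cell_type, qtt} -> {name -> genes}.
    """

    gene_positions: dict[str, Interval] = field(default_factory=dict)
    interval_sets: dict[str, list[Interval]] = field(default_factory=dict)
    gene_sets: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    GENE_SET_CATEGORIES = ("term", "cell_type", "qtt")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class NetworkParams:
    beta: int = 5
    min_module_size: int = 50
    deep_split: int = 0
    merge_height: float = 0.2
    calibration_quantile: float = 0.95

    def validate(self) -> None:
        if not (isinstance(self.beta, int) and self.beta >= 1):
            raise ConfigError("network.beta must be a positive integer")
        if self.min_module_size < 1:
            raise ConfigError("network.min_module_size must be positive")
        if self.deep_split not in (0, 1, 2, 3, 4):
            raise ConfigError("network.deep_split must be in {0,1,2,3,4}")
        if not 0 < self.merge_height < 1:
            raise ConfigError("network.merge_height must be in (0,1)")
        if not 0 < self.calibration_quantile < 1:
            raise ConfigError("network.calibration_quantile must be in (0,1)")


@dataclass
class PreservationParams:
    n_perm_z: int = 500
    n_perm_sig: int = 1000
    alpha: float = 0.05

    def validate(self) -> None:
        if self.n_perm_z < 100 or self.n_perm_sig < 100:
            raise ConfigError("preservation permutation counts must be >= 100")
        if not 0 < self.alpha < 1:
            raise ConfigError("preservation.alpha must be in (0,1)")


@dataclass
class DiffCorParams:
    n_perm: int = 100
    min_abs_ref_cor: float = 0.01
    alpha: float = 0.05

    def validate(self) -> None:
        if self.n_perm < 50:
            raise ConfigError("diffcor.n_perm must be >= 50")
        if not 0 <= self.min_abs_ref_cor < 0.2:
            raise ConfigError("diffcor.min_abs_ref_cor must be in [0, 0.2)")
        if not 0 < self.alpha < 1:
            raise ConfigError("diffcor.alpha must be in (0,1)")


@dataclass
class HubParams:
    kme_threshold: float = 0.85
    edge_threshold: float = 0.1
    top_n_degree: int = 5
    combine_rule: str = "min"  # kME combination across populations

    def validate(self) -> None:
        if not 0 < self.kme_threshold < 1:
            raise ConfigError("hubs.kme_threshold must be in (0,1)")
        if not 0 < self.edge_threshold < 1:
            raise ConfigError("hubs.edge_threshold must be in (0,1)")
        if self.top_n_degree < 1:
            raise ConfigError("hubs.top_n_degree must be >= 1")
        if self.combine_rule not in ("min", "mean"):
            raise ConfigError("hubs.combine_rule must be 'min' or 'mean'")


@dataclass
class EnrichmentParams:
    n_draws: int = 10000
    term_min: int = 11
    term_max: int = 499

    def validate(self) -> None:
        if self.n_draws < 1:
            raise ConfigError("enrichment.n_draws must be positive")
        if not 0 < self.term_min < self.term_max:
            raise ConfigError("enrichment.term_min must be < term_max, both positive")


@dataclass
class PreprocessParams:
    offset: float = 50.0
    negctrl_quantile: float = 0.98
    brightness_factor: float = 1.10
    min_sample_fraction: float = 0.10
    outlier_k_mad: float = 6.0

    def validate(self) -> None:
        if self.offset < 0:
            raise ConfigError("preprocess.offset must be >= 0")
        if not 0 < self.negctrl_quantile < 1:
            raise ConfigError("preprocess.negctrl_quantile must be in (0,1)")
        if self.brightness_factor <= 0:
            raise ConfigError("preprocess.brightness_factor must be positive")
        if not 0 < self.min_sample_fraction < 1:
            raise ConfigError("preprocess.min_sample_fraction must be in (0,1)")


@dataclass
class PipelineConfig:
    """Flat, sectioned pipeline configuration (section.key = value on disk)."""

    network: NetworkParams = field(default_factory=NetworkParams)
    preservation: PreservationParams = field(default_factory=PreservationParams)
    diffcor: DiffCorParams = field(default_factory=DiffCorParams)
    hubs: HubParams = field(default_factory=HubParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    seed: int = 0

    _SECTIONS = ("network", "preservation", "diffcor", "hubs", "enrichment", "preprocess")

    def validate(self) -> "PipelineConfig":
        for section in self._SECTIONS:
            getattr(self, section).validate()
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        return self


def _coerce(current, raw: str):
    if isinstance(current, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(current, int):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    return raw


def read_config(path: str | Path) -> PipelineConfig:
    """Parse a key=value config file; unknown keys are a hard error."""
    cfg = PipelineConfig()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key = value")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key == "seed":
                cfg.seed = int(raw)
                continue
            if "." not in key:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            section, name = key.split(".", 1)
            if section not in cfg._SECTIONS:
                raise ConfigError(f"{path}:{lineno}: unknown section {section!r}")
            params = getattr(cfg, section)
            if not hasattr(params, name):
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            setattr(params, name, _coerce(getattr(params, name), raw))
    return cfg.validate()


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"seed = {cfg.seed}\n")
        for section in cfg._SECTIONS:
            params = getattr(cfg, section)
            for f in dataclasses.fields(params):
                fh.write(f"{section}.{f.name} = {getattr(params, f.name)}\n")
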