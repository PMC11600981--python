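"""Readers/writers for the pipeline's external formats, run configuration and
the serialized fitted-model bundle.

Formats
-------
* expression TSV — first column ``gene``, one column per sample, log2(TPM+1)
* GMT — gene sets (name, description, tab-separated gene symbols)
* regulon TSV — columns ``source``, ``target``, ``weight`` (signed)
* pathway-weights TSV — ``gene`` column plus one column per pathway
* signature TSV — ``gene`` column plus one column per cell type
* survival TSV — columns ``sample``, ``time_days``, ``event``
* config YAML, model bundle JSON (versioned)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("tmeflow")

BUNDLE_FORMAT_VERSION = "1"


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger to write to standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper()))


# ---------------------------------------------------------------------------
# configuration and seeding
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline.

    Defaults follow the published analysis: features merged at correlation
    >= 0.70; hub TFs need module membership r > 0.8 and top-10% connectivity;
    top 20% most variable hub targets feed ORA; subgroup/module correlations
    kept at p < 0.05 with a dendrogram cut height of 5; the shadow-feature
    selector runs 100 seeds and keeps features confirmed in strictly more
    than 90% of them; risk groups split at the median linear predictor
    (0.66 for the large-cohort variant) and log-rank calls use alpha 0.01.
    """

    merge_threshold: float = 0.70
    zero_prop_max: float = 0.75
    min_variance: float = 1e-8
    soft_power: float = 6.0
    min_module_size: int = 5
    cut_quantile: float = 0.90
    kme_threshold: float = 0.80
    degree_quantile: float = 0.90
    target_variability_quantile: float = 0.80
    significance_alpha: float = 0.05
    cut_height: float = 5.0
    cut_mode: str = "quantile"   # "absolute" cuts at cut_height; "quantile" adapts to scale
    group_cut_quantile: float = 0.33
    boruta_repeats: int = 100
    boruta_confirm_frac: float = 0.90
    risk_quantile: float = 0.50
    logrank_alpha: float = 0.01
    rng_seed: int = 0

    def validate(self) -> "PipelineConfig":
        for name in ("zero_prop_max", "degree_quantile", "target_variability_quantile",
                     "significance_alpha", "boruta_confirm_frac", "risk_quantile",
                     "logrank_alpha", "cut_quantile", "group_cut_quantile"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"config field {name}={v} must lie in (0, 1)")
        if not -1.0 <= self.merge_threshold <= 1.0:
            raise ValueError("merge_threshold is a correlation and must lie in [-1, 1]")
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if self.min_module_size < 1 or self.boruta_repeats < 1:
            raise ValueError("min_module_size and boruta_repeats must be positive")
        if self.cut_mode not in ("absolute", "quantile"):
            raise ValueError("cut_mode must be 'absolute' or 'quantile'")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d)).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed.

        All randomness flows from ``rng_seed`` through named child streams so
        a stage can be re-run in isolation and reproduce its output.
        """
        return child_seed(self.rng_seed, stage)


def child_seed(root: int, stage: str) -> int:
    mix = zlib.crc32(stage.encode("utf-8"))
    return int(np.random.SeedSequence([int(root) & 0x7FFFFFFF, mix]).generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    if expr.index.has_duplicates:
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    if expr.columns.has_duplicates:
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes[:5]}")
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if (expr.values < 0).any():
        raise ValueError("expression values must be >= 0 (log2(TPM+1) scale)")
    return expr


def read_expression(path: str | Path, transform: str = "none") -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column ``gene``).

    Duplicate gene rows are collapsed by their mean. ``transform='log2_tpm1'``
    applies log2(x + 1) to a TPM-scale body.
    """
    if transform not in ("none", "log2_tpm1"):
        raise ValueError(f"unknown transform {transform!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) != len(set(header)):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate sample id(s) in header of {path}: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        bad = np.argwhere(body.isna().values)[0]
        raise ValueError(
            f"non-numeric value at gene {df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r} in {path}"
        )
    if body.index.has_duplicates:
        n = int(body.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by mean", n)
        body = body.groupby(level=0, sort=False).mean()
    if transform == "log2_tpm1":
        if (body.values < 0).any():
            raise ValueError("negative TPM values cannot be log-transformed")
        body = np.log2(body + 1.0)
    body.index.name = "gene"
    return validate_expression(body)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    out = expr.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with GMT semantics."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# regulons, pathway weights, signatures, survival
# ---------------------------------------------------------------------------

def read_regulons(path: str | Path) -> pd.DataFrame:
    reg = pd.read_csv(path, sep="\t")
    return validate_regulons(reg)


def validate_regulons(reg: pd.DataFrame) -> pd.DataFrame:
    missing = {"source", "target", "weight"} - set(reg.columns)
    if missing:
        raise ValueError(f"regulon table missing columns: {sorted(missing)}")
    if (reg["weight"] == 0).any():
        raise ValueError("regulon weights must be nonzero")
    if reg.duplicated(subset=["source", "target"]).any():
        dup = reg[reg.duplicated(subset=["source", "target"])].iloc[0]
        raise ValueError(f"duplicate regulon edge {dup['source']}->{dup['target']}")
    return reg.reset_index(drop=True)


def write_regulons(reg: pd.DataFrame, path: str | Path) -> None:
    reg[["source", "target", "weight"]].to_csv(path, sep="\t", index=False)


def filter_regulons(reg: pd.DataFrame, genes, min_targets: int = 5) -> pd.DataFrame:
    """Restrict edges to measured genes and drop TFs with < min_targets left."""
    genes = set(genes)
    kept = reg[reg["target"].isin(genes)]
    sizes = kept.groupby("source")["target"].size()
    small = sizes[sizes < min_targets].index
    if len(small):
        logger.info("dropping %d TFs with < %d usable targets", len(small), min_targets)
    return kept[~kept["source"].isin(small)].reset_index(drop=True)


def read_pathway_weights(path: str | Path) -> pd.DataFrame:
    w = pd.read_csv(path, sep="\t", index_col=0)
    return validate_pathway_weights(w)


def validate_pathway_weights(w: pd.DataFrame) -> pd.DataFrame:
    if w.columns.has_duplicates:
        raise ValueError("duplicate pathway names")
    nnz = (w != 0).sum(axis=0)
    bad = nnz[nnz < 2].index.tolist()
    if bad:
        raise ValueError(f"pathways with < 2 footprint genes: {bad}")
    return w


def write_pathway_weights(w: pd.DataFrame, path: str | Path) -> None:
    out = w.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_signature(path: str | Path) -> pd.DataFrame:
    sig = pd.read_csv(path, sep="\t", index_col=0)
    if sig.index.has_duplicates or sig.columns.has_duplicates:
        raise ValueError(f"duplicate gene or cell-type ids in signature {path}")
    return sig


def write_signature(sig: pd.DataFrame, path: str | Path) -> None:
    out = sig.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_survival(path: str | Path) -> pd.DataFrame:
    surv = pd.read_csv(path, sep="\t")
    missing = {"sample", "time_days", "event"} - set(surv.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    surv = surv.set_index("sample")
    return validate_survival(surv)


def validate_survival(surv: pd.DataFrame) -> pd.DataFrame:
    if surv.index.has_duplicates:
        raise ValueError("duplicate sample ids in survival table")
    if (surv["time_days"] < 0).any():
        raise ValueError("survival times must be >= 0")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event flags must be 0 or 1")
    return surv


def write_survival(surv: pd.DataFrame, path: str | Path) -> None:
    out = surv.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# fitted-model bundle
# ---------------------------------------------------------------------------

@dataclass
class FittedModelBundle:
    """Everything needed to project a fitted model into a new cohort.

    Stored as a versioned JSON document so a bundle remains inspectable by
    eye and diffable under version control.
    """

    config: dict = field(default_factory=dict)
    engines: list[str] = field(default_factory=list)
    signature_names: list[str] = field(default_factory=list)
    subgroups: list[dict] = field(default_factory=list)      # {subgroup_id, cell_type, members}
    modules: dict[str, list[str]] = field(default_factory=dict)
    module_orientations: dict[str, int] = field(default_factory=dict)
    module_groups: dict[str, list[str]] = field(default_factory=dict)
    cell_type_groups: list[dict] = field(default_factory=list)  # {group_id, module_group, members}
    selected_features: list[str] = field(default_factory=list)
    n_patient_clusters: int = 0
    format_version: str = BUNDLE_FORMAT_VERSION

    def referenced_features(self) -> list[str]:
        return sorted({m for sg in self.subgroups for m in sg["members"]})


def save_bundle(bundle: FittedModelBundle, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(bundle), fh, indent=1, sort_keys=True)


def load_bundle(path: str | Path) -> FittedModelBundle:
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"cannot parse model bundle {path}: {exc}") from exc
    version = data.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"model bundle {path} has format version {version!r}; this build reads {BUNDLE_FORMAT_VERSION!r}"
        )
    known = {f.name for f in dataclasses.fields(FittedModelBundle)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"model bundle {path} has unknown fields {sorted(unknown)}")
    return FittedModelBundle(**data)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
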