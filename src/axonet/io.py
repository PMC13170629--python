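"""File formats and run configuration.

Participant tables are tab-separated text with a header; connectivity
matrices are labeled dense CSV or matrix-market upper triangles (see
:mod:`axonet.connectome`); run configuration is a flat YAML file whose
defaults match the reference analysis (primary threshold t = 3.2, 10,000
permutations, alpha = .05, 73 volume tests, 7 component tests).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = ["read_participants", "write_participants", "RunConfig",
           "read_manifest", "write_manifest"]

_MANDATORY = ["id", "group", "nfl"]
_NUMERIC = ["age", "bmi", "bmi_sds", "nfl", "log_nfl", "leptin", "motion",
            "etiv", "edi_dt", "edi_bd", "bdi2", "illness_duration",
            "z_leptin", "conn_latent"]


def write_participants(path, cohort: pd.DataFrame) -> None:
    """Write a participant table as TSV (missing cells left empty)."""
    cohort.to_csv(path, sep="\t", index=False, na_rep="")


def read_participants(path) -> pd.DataFrame:
    """Read a participant TSV into a typed table.

    Mandatory columns: id, group, nfl. Unparseable numeric cells become
    missing with a logged warning; duplicate ids are an error. Censored
    leptin values are NOT imputed at read time (imputation is an explicit
    downstream step).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    if df["id"].duplicated().any():
        dups = df["id"][df["id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate participant ids {dups[:5]}")
    for col in df.columns:
        if col in ("id", "group"):
            continue
        if col == "leptin_censored":
            df[col] = df[col].map(
                {"True": True, "False": False, "1": True, "0": False})
            continue
        if col in _NUMERIC or col not in ("id", "group"):
            parsed = pd.to_numeric(df[col], errors="coerce")
            bad = parsed.isna() & df[col].notna() & (df[col].str.strip() != "")
            if bad.any():
                logger.warning("%s: %d unparseable cells in column %r set "
                               "to missing", path, int(bad.sum()), col)
            df[col] = parsed
    if (pd.to_numeric(df["nfl"], errors="coerce") <= 0).any():
        raise ValueError(f"{path}: nfl must be positive")
    return df


def write_manifest(path, mapping: dict[str, dict[str, str]]) -> None:
    """participant id -> {weight kind -> matrix file path} as JSON."""
    Path(path).write_text(json.dumps(mapping, indent=1, sort_keys=True))


def read_manifest(path) -> dict[str, dict[str, str]]:
    return json.loads(Path(path).read_text())


@dataclass
class RunConfig:
    """End-to-end pipeline configuration with reference defaults."""
    out_dir: str = "axonet_out"
    seed: int = 0
    # inputs: either synthetic generation or user files
    synthetic: bool = True
    n_per_group: int = 77
    n_nodes: int = 60
    participants_path: str | None = None
    manifest_path: str | None = None
    volumes_path: str | None = None
    # analysis parameters (defaults per the reference analysis)
    weight_kind: str = "FA"
    threshold: float = 3.2
    n_perm: int = 10000
    direction: str = "positive"
    alpha: float = 0.05
    nbs_covariates: tuple[str, ...] = ("wm_volume", "motion", "age")
    volume_tests: int = 73
    component_tests: int = 7
    group: str = "AN"
    # decided defaults, always declared in reports
    imputation_method: str = "lod_sqrt2"
    lod: float = 0.20
    estimator: str = "robust"
    fdr_method: str = "bh"
    qc_presence_threshold: float = 0.6
    qc_outlier_sd: float = 3.0
    qc_max_missing: float = 0.1
    n_boot: int = 5000
    outlier_sd_exclusion: float = 3.0

    def validate(self) -> None:
        if self.n_perm < 100:
            raise ValueError(
                "n_perm < 100 gives an unstable permutation null; "
                "use at least 100 (reference analysis: 10,000)")
        if self.weight_kind not in ("FA", "NOS"):
            raise ValueError("weight_kind must be FA or NOS")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.direction not in ("positive", "negative"):
            raise ValueError("direction must be positive or negative")
        if not self.synthetic:
            for name in ("participants_path", "manifest_path",
                         "volumes_path"):
                if getattr(self, name) is None:
                    raise ValueError(f"non-synthetic run requires {name}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "nbs_covariates" in raw:
            raw["nbs_covariates"] = tuple(raw["nbs_covariates"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["nbs_covariates"] = list(d["nbs_covariates"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
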