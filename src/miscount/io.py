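"""Dataset readers/writers and the run configuration format.

Datasets are comma-separated text with a header row and the columns
``unit, cluster, t, w1, w2, x, z1..zp`` (``unit`` and ``cluster``
optional).  Output files carry the seed and a configuration hash in
``#``-prefixed comment lines so every artifact states its provenance.
Run configuration is YAML with fixed sections; unknown keys are rejected
rather than ignored.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .inference import McmcSettings
from .model import ModelSpec, ObservedDataset, StructuralError
from .priors import PriorSpec

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_table",
    "RunConfig",
    "load_config",
    "save_config",
]

_REQUIRED = ("t", "w1", "w2", "x")


def read_dataset(path) -> ObservedDataset:
    """Read a delimited dataset, validating counts and person-time.

    Raises a parse error naming the offending row (0-based, excluding the
    header) and column.
    """
    df = pd.read_csv(path, comment="#")
    for col in _REQUIRED:
        if col not in df.columns:
            raise StructuralError(f"{path}: missing required column '{col}'")
    zcols = sorted(
        (c for c in df.columns if c.startswith("z") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    for col in ("w1", "w2"):
        vals = df[col]
        bad = vals.isna() | (vals != np.floor(vals)) | (vals < 0)
        if bad.any():
            row = int(bad.idxmax())
            raise StructuralError(
                f"{path}: column '{col}' row {row}: counts must be "
                f"nonnegative integers (got {vals.iloc[row]!r})"
            )
    bad_t = df["t"].isna() | (df["t"] <= 0)
    if bad_t.any():
        row = int(bad_t.idxmax())
        raise StructuralError(
            f"{path}: column 't' row {row}: person-time must be positive "
            f"(got {df['t'].iloc[row]!r})"
        )
    cluster = df["cluster"].to_numpy() if "cluster" in df.columns else None
    z = df[zcols].to_numpy() if zcols else np.empty((len(df), 0))
    return ObservedDataset(
        w1=df["w1"].to_numpy(dtype=np.int64),
        w2=df["w2"].to_numpy(dtype=np.int64),
        t=df["t"].to_numpy(dtype=float),
        x=df["x"].to_numpy(dtype=float),
        z=z,
        cluster=cluster,
    )


def _comment_header(meta: Optional[dict]) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_dataset(data: ObservedDataset, path, meta: Optional[dict] = None) -> None:
    """Write a dataset as CSV with an optional ``#`` metadata header."""
    df = pd.DataFrame(
        {
            "unit": np.arange(data.n),
            "t": data.t,
            "w1": data.w1,
            "w2": data.w2,
            "x": data.x,
        }
    )
    if data.cluster is not None:
        df.insert(1, "cluster", data.cluster)
    for j in range(data.p):
        df[f"z{j + 1}"] = data.z[:, j]
    with open(path, "w") as fh:
        fh.write(_comment_header(meta))
        df.to_csv(fh, index=False)


def write_table(df: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    """Write any report table as CSV with a ``#`` metadata header."""
    with open(path, "w") as fh:
        fh.write(_comment_header(meta))
        df.to_csv(fh)


@dataclass
class RunConfig:
    """One run's model, priors, sampler settings and study parameters."""

    seed: int = 0
    model: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    study: dict = field(default_factory=dict)
    sensitivity: dict = field(default_factory=dict)

    _SECTIONS = ("model", "priors", "mcmc", "study", "sensitivity")
    _STUDY_KEYS = {
        "R", "sigma2", "se_true", "sp_true", "scenario", "track",
        "sp_beta_low",
    }
    _SENS_KEYS = {"pairs", "parameter"}

    def model_spec(self) -> ModelSpec:
        return ModelSpec(**self.model)

    def prior_spec(self) -> PriorSpec:
        kw = dict(self.priors)
        for key in ("se_beta", "sp_beta"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return PriorSpec(**kw)

    def mcmc_settings(self) -> McmcSettings:
        return McmcSettings(seed=self.seed, **self.mcmc)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - set(cls._SECTIONS) - {"seed"}
        if unknown:
            raise StructuralError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(
            seed=int(d.get("seed", 0)),
            **{s: dict(d.get(s) or {}) for s in cls._SECTIONS},
        )
        # constructing the typed objects validates section contents
        if cfg.model:
            cfg.model_spec()
        if cfg.priors:
            cfg.prior_spec()
        if cfg.mcmc:
            cfg.mcmc_settings()
        bad = set(cfg.study) - cls._STUDY_KEYS
        if bad:
            raise StructuralError(f"unknown study keys: {sorted(bad)}")
        bad = set(cfg.sensitivity) - cls._SENS_KEYS
        if bad:
            raise StructuralError(f"unknown sensitivity keys: {sorted(bad)}")
        return cfg

    def digest(self) -> str:
        """Short stable hash of the canonicalized configuration."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise StructuralError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(raw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
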