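"""CSV / YAML interchange for datasets, configuration and chain output.

Dataset CSV layout: a header row with covariate columns ``X1..XJ``
holding 1-based integer categories, an optional binary column ``Y`` and
optional real fixed-effect columns ``W1..WL``.  The 1-based category
convention exists only in files; everything in memory is 0-based.

A chain directory holds ``alloc.csv`` (one row per kept sweep, one
column per subject, 1-based labels), ``scalars.csv`` (per-sweep alpha,
cluster count, log likelihood, optional log marginal partition
posterior, move acceptance flags) and ``meta.yaml`` (config and
version); ``params.json`` is added when parameter storage is on.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import Dataset, PriorSpec
from .sampler import ChainOutput, SamplerConfig

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_config",
    "write_chain",
    "read_chain",
]


def _numbered(columns, prefix: str) -> list[str]:
    pat = re.compile(rf"^{prefix}(\d+)$")
    hits = sorted((int(pat.match(c).group(1)), c) for c in columns if pat.match(c))
    if hits and [h[0] for h in hits] != list(range(1, len(hits) + 1)):
        raise ValueError(f"{prefix} columns must be numbered consecutively from 1")
    return [c for _, c in hits]


def read_dataset(path) -> Dataset:
    """Read a dataset CSV (columns X1..XJ, optional Y, optional W1..WL)."""
    df = pd.read_csv(path)
    xcols = _numbered(df.columns, "X")
    if not xcols and "Y" not in df.columns:
        raise ValueError("no covariate columns X1..XJ and no response column Y")
    sub = df[xcols + (["Y"] if "Y" in df.columns else [])
             + _numbered(df.columns, "W")]
    if sub.isna().any().any():
        raise ValueError("missing values are not supported; remove or impute "
                         "incomplete rows before running the sampler")
    X = df[xcols].to_numpy(dtype=np.int64) - 1  # 1-based on disk
    if X.size and X.min() < 0:
        raise ValueError("categories in files must be 1-based positive integers")
    Y = df["Y"].to_numpy(dtype=np.int64) if "Y" in df.columns else None
    wcols = _numbered(df.columns, "W")
    W = df[wcols].to_numpy(dtype=np.float64) if wcols else None
    return Dataset(X=X, Y=Y, W=W)


def write_dataset(data: Dataset, path) -> None:
    """Write a dataset CSV with 1-based categories."""
    cols = {f"X{j + 1}": data.X[:, j] + 1 for j in range(data.J)}
    if data.Y is not None:
        cols["Y"] = data.Y
    if data.W is not None:
        for l in range(data.L):
            cols[f"W{l + 1}"] = data.W[:, l]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_config(path) -> tuple[PriorSpec, SamplerConfig]:
    """Read a YAML file with optional ``priors`` and ``sampler`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    priors = PriorSpec(**(raw.get("priors") or {}))
    cfg_raw = raw.get("sampler") or {}
    if "moves_enabled" in cfg_raw:
        cfg_raw["moves_enabled"] = tuple(bool(m) for m in cfg_raw["moves_enabled"])
    cfg = SamplerConfig(**cfg_raw)
    return priors, cfg


def write_chain(chain: ChainOutput, outdir) -> None:
    """Persist a chain to a directory of plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(chain.Z + 1).to_csv(out / "alloc.csv", index=False,
                                     header=[f"Z{i + 1}" for i in range(chain.Z.shape[1])])
    scalars = pd.DataFrame({
        "sweep": np.arange(chain.n_sweeps),
        "alpha": chain.alpha,
        "K_occ": chain.K_occ,
        "loglik": chain.loglik,
        "log_mpp": chain.log_mpp if chain.log_mpp is not None
                   else np.full(chain.n_sweeps, np.nan),
        "accept_move1": chain.accept[:, 0],
        "accept_move2": chain.accept[:, 1],
        "accept_move3": chain.accept[:, 2],
    })
    scalars.to_csv(out / "scalars.csv", index=False)
    meta = {"version": chain.version, "config": asdict(chain.config)}
    meta["config"]["moves_enabled"] = list(chain.config.moves_enabled)
    with open(out / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    if chain.params is not None:
        payload = [{"psi": r["psi"].tolist(),
                    "theta": r["theta"].tolist(),
                    "phi": [[p.tolist() for p in comp] for comp in r["phi"]],
                    "beta": r["beta"].tolist()} for r in chain.params]
        with open(out / "params.json", "w") as fh:
            json.dump(payload, fh)


def read_chain(chaindir) -> ChainOutput:
    """Load a chain directory written by :func:`write_chain`."""
    d = Path(chaindir)
    Z = pd.read_csv(d / "alloc.csv").to_numpy(dtype=np.int64) - 1
    sc = pd.read_csv(d / "scalars.csv")
    with open(d / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    cfg_raw = meta["config"]
    cfg_raw["moves_enabled"] = tuple(cfg_raw["moves_enabled"])
    cfg = SamplerConfig(**cfg_raw)
    log_mpp = sc["log_mpp"].to_numpy()
    params = None
    if (d / "params.json").exists():
        with open(d / "params.json") as fh:
            raw = json.load(fh)
        params = [{"psi": np.asarray(r["psi"]),
                   "theta": np.asarray(r["theta"]),
                   "phi": [[np.asarray(p) for p in comp] for comp in r["phi"]],
                   "beta": np.asarray(r["beta"])} for r in raw]
    return ChainOutput(
        Z=Z,
        alpha=sc["alpha"].to_numpy(),
        K_occ=sc["K_occ"].to_numpy(dtype=np.int64),
        loglik=sc["loglik"].to_numpy(),
        log_mpp=None if np.isnan(log_mpp).all() else log_mpp,
        accept=sc[["accept_move1", "accept_move2", "accept_move3"]].to_numpy(),
        config=cfg,
        version=meta.get("version", ""),
        params=params,
    )
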