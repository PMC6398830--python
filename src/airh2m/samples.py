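"""Posterior-sample container with burn-in bookkeeping and diagnostics."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import gelman_rubin, mc_error

__all__ = ["PosteriorSamples"]


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, one array of shape (n_chains, n_keep, ...) per parameter.

    ``meta`` records configs, seed and model variant; ``extras`` holds
    non-draw artifacts (posterior-mean latent fields, deviance at the
    posterior-mean predictor, imputation summaries).
    """

    draws: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {v.shape[:2] for v in self.draws.values()}
        if len(lengths) > 1:
            raise ValueError("all parameters must share (n_chains, n_keep)")

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_keep(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws pooled over chains: shape (n_chains * n_keep, ...)."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def scalar_names(self) -> list[str]:
        """Flattened scalar parameter labels, e.g. ``beta[2]``."""
        out = []
        for name, a in self.draws.items():
            extra = a.shape[2:]
            if extra == ():
                out.append(name)
            else:
                for idx in np.ndindex(*extra):
                    out.append(f"{name}[{','.join(str(i) for i in idx)}]")
        return out

    def _scalar_chains(self, label: str) -> np.ndarray:
        if "[" in label:
            name, idx = label[:-1].split("[")
            ind = tuple(int(i) for i in idx.split(","))
            return self.draws[name][(slice(None), slice(None)) + ind]
        return self.draws[label]

    def diagnostics(self) -> pd.DataFrame:
        """Per-scalar Gelman-Rubin statistic and MC-error / posterior-sd ratio."""
        rows = []
        for label in self.scalar_names():
            ch = self._scalar_chains(label)
            pooled = ch.ravel()
            sd = np.std(pooled, ddof=1)
            ratio = mc_error(pooled) / sd if sd > 0 else 0.0
            rhat = gelman_rubin(ch) if self.n_chains >= 2 else np.nan
            rows.append({"parameter": label, "rhat": rhat, "mc_error_ratio": ratio})
        return pd.DataFrame(rows).set_index("parameter")

    def summary(self, name: str) -> pd.DataFrame:
        """Posterior mean, sd and equal-tailed 95% interval per component."""
        a = self.get(name)
        flat = a.reshape(len(a), -1)
        return pd.DataFrame({
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "lo95": np.percentile(flat, 2.5, axis=0),
            "hi95": np.percentile(flat, 97.5, axis=0),
        })

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: chain, iteration, parameter, value."""
        frames = []
        for label in self.scalar_names():
            ch = self._scalar_chains(label)
            m, n = ch.shape
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(m), n),
                "iteration": np.tile(np.arange(n), m),
                "parameter": label,
                "value": ch.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)

    def save(self, csv_path, manifest_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if manifest_path is not None:
            diag = self.diagnostics()
            manifest = {
                "meta": _jsonable(self.meta),
                "diagnostics": {
                    "max_rhat": None if diag["rhat"].isna().all()
                    else float(diag["rhat"].max()),
                    "max_mc_error_ratio": float(diag["mc_error_ratio"].max()),
                },
            }
            with open(manifest_path, "w") as fh:
                json.dump(manifest, fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "__dict__") and not isinstance(obj, (str, bytes)):
        try:
            return _jsonable(vars(obj))
        except TypeError:
            return str(obj)
    return obj
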