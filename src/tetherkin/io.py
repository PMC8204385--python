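"""Sensorgram readers/writers and run configuration.

Traces are plain delimited text: either a headerless two-column CSV
(time, signal) or a tab-separated export with a header line.  Metadata
(concentrations, injection timing, ground truth for synthetic traces)
travels in a JSON sidecar or in the :class:`SPRTrace` object itself.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["SPRTrace", "read_trace", "write_trace", "RunConfig"]


@dataclass
class SPRTrace:
    """A measured or synthetic sensorgram.

    ``times`` in seconds (strictly increasing), ``signal`` in response
    units, ``metadata`` free-form (conditions, flow-cell label,
    reference-subtracted flag, ground truth...).
    """

    times: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise ValueError("times and signal must be equal-length 1D arrays")
        if self.times.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if np.any(np.isnan(self.times)) or np.any(np.isnan(self.signal)):
            raise ValueError("NaN values are not allowed in a trace")
        if np.any(np.diff(self.times) <= 0):
            bad = int(np.argmax(np.diff(self.times) <= 0)) + 1
            raise ValueError(f"times must be strictly increasing (row {bad})")

    def __len__(self) -> int:
        return self.times.size

    def segment(self, t_min: float = -np.inf, t_max: float = np.inf) -> "SPRTrace":
        m = (self.times >= t_min) & (self.times <= t_max)
        return SPRTrace(self.times[m], self.signal[m], dict(self.metadata))


def read_trace(path, dialect: str = "auto") -> SPRTrace:
    """Parse a sensorgram file.

    ``dialect``: ``"csv"`` (headerless two-column CSV), ``"tsv"``
    (tab-separated with a header) or ``"auto"``.  Time units are
    seconds.  A JSON sidecar ``<path>.meta.json`` is loaded into the
    metadata when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        first = path.open().readline()
        dialect = "tsv" if "\t" in first else "csv"
    if dialect == "csv":
        df = pd.read_csv(path, header=None, comment="#")
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, signal)")
    df = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: non-numeric or missing value at row {row}")
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return SPRTrace(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), meta)


def write_trace(trace: SPRTrace, path, dialect: str = "csv") -> None:
    """Write a trace (and its metadata sidecar when non-empty)."""
    path = Path(path)
    df = pd.DataFrame({"time": trace.times, "signal": trace.signal})
    if dialect == "csv":
        df.to_csv(path, header=False, index=False)
    elif dialect == "tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if trace.metadata:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(trace.metadata, indent=1, default=float))


@dataclass
class RunConfig:
    """Validated configuration for the pipeline commands.

    Defaults follow the package's documented choices; CLI flags override
    file values.
    """

    # PDE grid / solver
    r_max: float = 6.0
    n_nodes: int = 96
    rtol: float = 1e-6
    atol: float = 1e-8
    # simulated annealing
    sa_steps: int = 100_000
    sa_restarts: int = 3
    # MCMC
    mcmc_max_len: int = 4000
    mcmc_level: float = 0.05
    # reach regression
    exclude_peg: tuple = (0,)
    weighted_regression: bool = False
    # general
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.r_max < 5 or self.n_nodes < 64:
            raise ValueError("grid must satisfy r_max >= 5 and n_nodes >= 64")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")
        if self.sa_steps < 1000 or self.sa_restarts < 1:
            raise ValueError("sa_steps >= 1000 and sa_restarts >= 1 required")
        if self.mcmc_max_len < 40 or not 0 < self.mcmc_level < 1:
            raise ValueError("invalid MCMC settings")

    @classmethod
    def load(cls, path, **overrides) -> "RunConfig":
        """Load from a YAML file; keyword overrides take precedence."""
        data = {}
        if path is not None:
            raw = yaml.safe_load(Path(path).read_text()) or {}
            valid = {f.name for f in dataclasses.fields(cls)}
            unknown = set(raw) - valid
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            data.update(raw)
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "exclude_peg" in data:
            data["exclude_peg"] = tuple(data["exclude_peg"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclude_peg"] = list(d["exclude_peg"])
        return d
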