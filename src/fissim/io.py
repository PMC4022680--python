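"""Configuration files, result persistence, network snapshots, fixtures.

Formats are deliberately plain: batch results round-trip through a tidy
CSV (one row per replicate), network snapshots through a directed
edge-list CSV (``day,source,target,weight``) with optional GraphML via
networkx, and sweep configurations through YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import (
    BATCH_COLUMNS,
    FISSION_THRESHOLD,
    MAX_DAYS,
    MIN_SUBGROUP,
    BatchResult,
    replicate_seed,
)
from .errors import ConfigurationError
from .movement import Condition
from .network import DayAssignment, SocialNetwork, init_egalitarian, transfer_update

#: fixed float formatting for byte-stable CSV output; 12 significant digits
#: round-trip link weights precisely enough to re-verify the row-sum invariant
FLOAT_FORMAT = "%.12g"


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SweepConfig:
    """A validated sweep: condition grid plus engine settings."""

    grid: tuple[Condition, ...]
    reps: int = 1000
    base_seed: int = 0
    max_days: int = MAX_DAYS
    threshold: float = FISSION_THRESHOLD
    min_subgroup: int = MIN_SUBGROUP
    day_mode: str = "single_pass"


def load_config(path: str | Path) -> SweepConfig:
    """Load and validate a YAML sweep configuration.

    Two grid styles are accepted: an explicit ``conditions`` list of
    mappings with keys ``n, C, lambda1, lambda2, transfer``, or a
    factorial ``grid`` block with ``n``, ``transfer`` lists and
    ``lambda_pairs`` (list of ``[C, lambda]`` rows; defaults to the study
    design).  The feasibility rule ``(lambda1 + lambda2) <= 1 - C*100`` is
    enforced per condition at load time.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    extra = {}
    for key in ("preference", "redraw_daily"):
        if key in raw:
            extra[key] = raw[key]
    conds: list[Condition] = []
    if "conditions" in raw:
        for idx, item in enumerate(raw["conditions"]):
            try:
                conds.append(Condition(
                    n=int(item["n"]), C=float(item["C"]),
                    lambda1=float(item["lambda1"]), lambda2=float(item["lambda2"]),
                    transfer=float(item["transfer"]), **extra,
                ))
            except (KeyError, ConfigurationError) as exc:
                raise ConfigurationError(
                    f"{path}: condition #{idx} invalid ({item!r}): {exc}; "
                    "remember (lambda1 + lambda2) <= 1 - C*100"
                ) from exc
    elif "grid" in raw:
        g = raw["grid"]
        n_values = [int(v) for v in g.get("n", [10, 20])]
        transfers = [float(t) for t in g.get("transfer", list(range(10, 101, 10)))]
        pairs = [(float(c), float(l)) for c, l in g.get(
            "lambda_pairs",
            [[0.001, 0.45], [0.002, 0.40], [0.003, 0.35], [0.004, 0.30],
             [0.005, 0.25], [0.006, 0.20], [0.007, 0.15], [0.008, 0.10],
             [0.009, 0.05]],
        )]
        try:
            conds = [
                Condition(n=n, C=C, lambda1=lam, lambda2=lam, transfer=T, **extra)
                for n in n_values for (C, lam) in pairs for T in transfers
            ]
        except ConfigurationError as exc:
            raise ConfigurationError(
                f"{path}: grid produced an invalid condition: {exc}; "
                "remember (lambda1 + lambda2) <= 1 - C*100"
            ) from exc
    else:
        raise ConfigurationError(f"{path}: needs a 'conditions' list or a 'grid' block")
    if not conds:
        raise ConfigurationError(f"{path}: empty condition grid")
    return SweepConfig(
        grid=tuple(conds),
        reps=int(raw.get("reps", 1000)),
        base_seed=int(raw.get("base_seed", 0)),
        max_days=int(raw.get("max_days", MAX_DAYS)),
        threshold=float(raw.get("threshold", FISSION_THRESHOLD)),
        min_subgroup=int(raw.get("min_subgroup", MIN_SUBGROUP)),
        day_mode=str(raw.get("day_mode", "single_pass")),
    )


# ---------------------------------------------------------------------------
# batch results

def write_results(batch: BatchResult, path: str | Path) -> None:
    """Write the tidy batch table as CSV (stable ordering and float format,
    so identical batches produce identical bytes)."""
    table = batch.table.sort_values(
        ["n", "C", "transfer", "replicate"], kind="mergesort"
    ).reset_index(drop=True)
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_results(path: str | Path) -> BatchResult:
    """Read a batch CSV back; schema mismatches raise with the missing column."""
    table = pd.read_csv(path)
    missing = [c for c in BATCH_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing column(s) {missing}")
    table["censored"] = table["censored"].astype(bool)
    return BatchResult(table)


# ---------------------------------------------------------------------------
# network snapshots

def write_network(
    net: SocialNetwork, path: str | Path, day: int = 0
) -> None:
    """Directed weighted edge-list CSV with header ``day,source,target,weight``
    (0-based integer individual ids; self-links omitted)."""
    rows = []
    for i in range(net.n):
        for k in range(net.n):
            if i != k:
                rows.append((day, i, k, net.weights[i, k]))
    pd.DataFrame(rows, columns=["day", "source", "target", "weight"]).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_network(path: str | Path) -> SocialNetwork:
    """Read an edge-list CSV back into a network (full precision)."""
    table = pd.read_csv(path)
    missing = [c for c in ("source", "target", "weight") if c not in table.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing column(s) {missing}")
    n = int(max(table["source"].max(), table["target"].max())) + 1
    w = np.zeros((n, n))
    w[table["source"].to_numpy(int), table["target"].to_numpy(int)] = (
        table["weight"].to_numpy(float)
    )
    return SocialNetwork(w)


def write_network_graphml(net: SocialNetwork, path: str | Path) -> None:
    """GraphML export of the directed weighted grooming network."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(net.n))
    for i in range(net.n):
        for k in range(net.n):
            if i != k:
                g.add_edge(i, k, weight=float(net.weights[i, k]))
    nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# run manifest

@dataclass(frozen=True)
class RunManifest:
    """Everything needed to bit-reproduce a batch."""

    base_seed: int
    reps: int
    conditions: tuple[dict[str, Any], ...]
    max_days: int = MAX_DAYS
    threshold: float = FISSION_THRESHOLD
    min_subgroup: int = MIN_SUBGROUP
    day_mode: str = "single_pass"
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @classmethod
    def from_sweep(cls, cfg: SweepConfig) -> "RunManifest":
        fields = ("n", "C", "lambda1", "lambda2", "transfer",
                  "preference", "redraw_daily")
        return cls(
            base_seed=cfg.base_seed, reps=cfg.reps,
            conditions=tuple({f: getattr(c, f) for f in fields} for c in cfg.grid),
            max_days=cfg.max_days, threshold=cfg.threshold,
            min_subgroup=cfg.min_subgroup, day_mode=cfg.day_mode,
        )

    def condition_seeds(self, condition_index: int) -> list[int]:
        return [
            replicate_seed(self.base_seed, condition_index, r)
            for r in range(self.reps)
        ]

    def write(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "timestamp": self.timestamp,
            "base_seed": self.base_seed,
            "reps": self.reps,
            "max_days": self.max_days,
            "threshold": self.threshold,
            "min_subgroup": self.min_subgroup,
            "day_mode": self.day_mode,
            "conditions": list(self.conditions),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# fixtures

def make_fixture(
    kind: str,
    n: int,
    *,
    split: tuple[int, int] | None = None,
    transfer: float = 50.0,
    steps: int = 5,
    target_within: float = 92.5,
    seed: int = 0,
) -> SocialNetwork:
    """Deterministic test networks.

    - ``egalitarian``: the seed network itself.
    - ``pre_clustered``: ``steps`` transfer updates applied to the
      egalitarian network with a fixed split (default half/half), so
      cross-subgroup links have decayed geometrically by
      ``(1 - transfer/100)**steps``.
    - ``near_fission``: a clustered network whose within-subgroup sums sit
      at ``target_within`` (default 92.5, inside [90, 95)), for boundary
      tests of the irreversible-fission threshold.
    """
    if n < 2:
        raise ConfigurationError(f"group size must be >= 2, got {n!r}")
    if kind == "egalitarian":
        return init_egalitarian(n)
    if split is None:
        split = (n // 2, n - n // 2)
    if split[0] + split[1] != n or min(split) < 1:
        raise ConfigurationError(f"split {split!r} incompatible with n={n}")
    areas = np.array([1] * split[0] + [2] * split[1], dtype=np.int8)
    assign = DayAssignment(areas)
    if kind == "pre_clustered":
        net = init_egalitarian(n)
        for _ in range(steps):
            net = transfer_update(net, assign, transfer)
        return net
    if kind == "near_fission":
        if not 0.0 <= target_within < 100.0:
            raise ConfigurationError("target_within must lie in [0, 100)")
        if min(split) < 2:
            raise ConfigurationError(
                "near_fission needs >= 2 individuals per subgroup"
            )
        w = np.zeros((n, n))
        for i in range(n):
            same = (areas == areas[i])
            same[i] = False
            cross = ~same
            cross[i] = False
            w[i, same] = target_within / same.sum()
            w[i, cross] = (100.0 - target_within) / cross.sum()
        return SocialNetwork(w)
    raise ConfigurationError(f"unknown fixture kind {kind!r}")
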