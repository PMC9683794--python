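"""Aggregation of simulation logs, figure-style tables, and file I/O.

Everything is written as comma-separated UTF-8 text with '.' decimals and a
self-describing block of '#'-prefixed header comments; floats use %.17g so a
written table reads back bit-exact.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from .config import EffectSizeDistribution

__all__ = [
    "RunManifest",
    "write_table",
    "read_table",
    "contribution_from_fixations",
    "turnover_summary",
    "write_experiment",
    "file_checksum",
]


def file_checksum(path) -> str:
    return "sha256:" + hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one experiment directory."""

    parameters: dict
    seeds: list
    engine: str
    n_replicates: int
    warnings: list = field(default_factory=list)
    software_version: str = ""
    started: str = ""
    finished: str = ""
    outputs: dict = field(default_factory=dict)  # filename -> checksum

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """CSV with '#'-comment header; numeric round-trip is exact."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write(f"# columns: {','.join(map(str, df.columns))}\n")
        # repr is the shortest exact round-trip representation of a float
        df.to_csv(fh, index=False, float_format=lambda v: repr(float(v)),
                  lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"malformed table file {path}: {exc}") from exc


def _bin_probability(dist: EffectSizeDistribution, lo: float, hi: float) -> float:
    if dist.family == "exponential_in_S":
        m = dist.mean_S
        return float(np.exp(-lo / m) - np.exp(-hi / m))
    if dist.family == "point_mass":
        return float(lo <= dist.mean_S < hi)
    inside = (dist.S_values >= lo) & (dist.S_values < hi)
    return float(dist.weights[inside].sum())


def contribution_from_fixations(fixations: pd.DataFrame,
                                dist: EffectSizeDistribution,
                                twoNU: float, S_bins) -> pd.DataFrame:
    """Per-effect-size-bin fixed contribution per unit mutational input.

    For each bin of S = a^2, sums the signed phenotypic contribution 2a over
    post-shift fixations and divides by the mutational input into the bin
    (2NU times the probability mass of the bin under g), split by origin
    (segregating at the shift vs arisen after).  Over a long horizon the
    bin-wise totals are directly comparable to the analytic long-term curve
    (1+C) Lambda f(a) / V_A(0), and their input-weighted sum approaches
    Lambda.  Bins with no fixations report NaN with count 0.
    """
    S_bins = np.asarray(S_bins, dtype=float)
    post = fixations[fixations["t_fix"] >= 0]
    S = post["a"].to_numpy() ** 2
    contrib = 2.0 * post["a"].to_numpy()
    standing = (post["origin"] == "standing").to_numpy()
    rows = []
    for lo, hi in zip(S_bins[:-1], S_bins[1:]):
        inside = (S >= lo) & (S < hi)
        n = int(inside.sum())
        p_bin = _bin_probability(dist, lo, hi)
        denom = twoNU * p_bin
        if n == 0 or denom == 0:
            dz_tot = dz_st = dz_new = np.nan
        else:
            dz_tot = contrib[inside].sum() / denom
            dz_st = contrib[inside & standing].sum() / denom
            dz_new = contrib[inside & ~standing].sum() / denom
        rows.append({
            "S_lo": lo, "S_hi": hi, "n_fixations": n,
            "dz_total": dz_tot, "dz_standing": dz_st, "dz_new": dz_new,
            "input_probability": p_bin,
        })
    return pd.DataFrame(rows)


def turnover_summary(rapid_table: pd.DataFrame,
                     longterm_table: pd.DataFrame) -> pd.DataFrame:
    """Short- vs long-term contribution per bin and their difference.

    Both tables must share identical (S_lo, S_hi) bins and carry a
    ``dz`` column (contribution per unit mutational input) plus
    ``input_probability``.  The input-weighted positive and negative areas of
    the difference balance when the long horizon captures the full turnover.
    """
    for col in ("S_lo", "S_hi", "dz", "input_probability"):
        if col not in rapid_table or col not in longterm_table:
            raise ValueError(f"both tables need a {col!r} column")
    if (not np.array_equal(rapid_table["S_lo"], longterm_table["S_lo"])
            or not np.array_equal(rapid_table["S_hi"], longterm_table["S_hi"])):
        raise ValueError("tables are binned differently")
    out = rapid_table[["S_lo", "S_hi", "input_probability"]].copy()
    out["dz_short"] = rapid_table["dz"].to_numpy()
    out["dz_long"] = longterm_table["dz"].to_numpy()
    out["difference"] = out["dz_long"] - out["dz_short"]
    return out


def write_experiment(config, rs) -> RunManifest:
    """Write trajectory.csv, fixations.csv and manifest.json for a run."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    p = config.params
    meta = {
        "engine": config.engine, "N": p.N, "U": p.U, "VS": p.VS,
        "Lambda": p.Lambda, "seed": p.seed, "burn_in": p.burn_in,
        "horizon": p.horizon, "n_replicates": config.n_replicates,
        "dist_family": config.dist.family, "dist_mean_S": config.dist.mean_S,
        "VA0_measured": rs.VA0_measured,
    }
    write_table(rs.summary(), out / "trajectory.csv", meta)
    write_table(rs.fixations, out / "fixations.csv", meta)
    try:
        ver = _pkg_version("polyshift")
    except Exception:  # not installed (e.g. run from a checkout)
        ver = "unknown"
    manifest = RunManifest(
        parameters=meta, seeds=rs.seeds, engine=config.engine,
        n_replicates=config.n_replicates,
        warnings=[f"replicate {r} failed" for r in rs.failures],
        software_version=ver, started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        outputs={name: file_checksum(out / name)
                 for name in ("trajectory.csv", "fixations.csv")},
    )
    manifest.write(out / "manifest.json")
    return manifest
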