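"""Readers and writers for the plain-text interchange formats.

Traces travel as two-column TSV (time_s, current_pA) with a '#'-prefixed
key=value metadata header, or as a .npy array with a JSON metadata sidecar
for long recordings.  Histograms, idealized event lists, I/V tables, helix
span configs and pore profiles are all simple TSV; mixture fits and gating
reports serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .amplitude_histogram import AmplitudeHistogram, MixtureFit
from .channel_sim import Trace
from .idealization import IdealizedRecord
from .iv_selectivity import IVDataset

__all__ = [
    "write_trace_tsv",
    "read_trace_tsv",
    "write_trace_npy",
    "read_trace_npy",
    "write_histogram_tsv",
    "read_histogram_tsv",
    "write_mixture_json",
    "write_events_tsv",
    "read_events_tsv",
    "read_iv_tsv",
    "write_iv_tsv",
    "read_spans_tsv",
    "read_pore_profile_tsv",
]


def _trace_metadata(trace: Trace) -> dict:
    meta = {
        "sampling_rate": trace.sampling_rate,
        "holding_potential_mV": trace.holding_potential,
        "filter_cutoff": trace.filter_cutoff,
        "seed": trace.seed,
    }
    meta.update({k: v for k, v in trace.metadata.items() if isinstance(v, (int, float, str))})
    return meta


def write_trace_tsv(trace: Trace, path) -> None:
    with open(path, "w") as fh:
        for key, val in _trace_metadata(trace).items():
            fh.write(f"# {key}={val}\n")
        fh.write("time_s\tcurrent_pA\n")
        np.savetxt(fh, np.column_stack([trace.times, trace.samples]), fmt="%.7g", delimiter="\t")


def read_trace_tsv(path) -> Trace:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    data = pd.read_csv(path, sep="\t", comment="#")
    times = data["time_s"].to_numpy(dtype=float)
    dt = float(meta.get("sampling_rate", 0)) ** -1 if meta.get("sampling_rate") else float(times[1] - times[0])
    fc = meta.get("filter_cutoff")
    return Trace(
        samples=data["current_pA"].to_numpy(dtype=float),
        dt=dt,
        holding_potential=float(meta.get("holding_potential_mV", 0.0)),
        seed=int(meta["seed"]) if meta.get("seed", "None") not in ("None", "") else None,
        filter_cutoff=None if fc in (None, "None", "") else float(fc),
    )


def write_trace_npy(trace: Trace, path) -> None:
    """Binary array container: <path>.npy samples + <path>.json metadata."""
    base = Path(path).with_suffix("")
    np.save(base.with_suffix(".npy"), trace.samples)
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(_trace_metadata(trace), fh, indent=1)


def read_trace_npy(path) -> Trace:
    base = Path(path).with_suffix("")
    samples = np.load(base.with_suffix(".npy"))
    with open(base.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return Trace(
        samples=samples,
        dt=1.0 / float(meta["sampling_rate"]),
        holding_potential=float(meta.get("holding_potential_mV", 0.0)),
        seed=meta.get("seed"),
        filter_cutoff=meta.get("filter_cutoff"),
    )


def write_histogram_tsv(hist: AmplitudeHistogram, path) -> None:
    df = pd.DataFrame(
        {
            "bin_left_pA": hist.bin_edges[:-1],
            "bin_right_pA": hist.bin_edges[1:],
            "count": hist.counts,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_histogram_tsv(path) -> AmplitudeHistogram:
    df = pd.read_csv(path, sep="\t")
    edges = np.concatenate([df["bin_left_pA"].to_numpy(dtype=float), [float(df["bin_right_pA"].iloc[-1])]])
    counts = df["count"].to_numpy(dtype=int)
    return AmplitudeHistogram(bin_edges=edges, counts=counts, n_samples=int(counts.sum()))


def write_mixture_json(fit: MixtureFit, path) -> None:
    payload = {
        "k": fit.k,
        "components": [
            {"mean_pA": m, "sd_pA": s, "area": a} for m, s, a in fit.components
        ],
        "rss": fit.rss,
        "converged": fit.converged,
        "degenerate_components": fit.degenerate,
        "shared_sd": fit.shared_sd,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_events_tsv(record: IdealizedRecord, path) -> None:
    df = pd.DataFrame(
        {"level": record.levels, "start_s": record.starts, "duration_s": record.durations}
    )
    with open(path, "w") as fh:
        fh.write(f"# n_levels={record.n_levels}\n")
        fh.write(f"# dead_time_s={record.dead_time}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def read_events_tsv(path) -> IdealizedRecord:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    durations = df["duration_s"].to_numpy(dtype=float)
    n_levels = int(meta.get("n_levels", df["level"].max() + 1))
    return IdealizedRecord(
        levels=df["level"].to_numpy(dtype=int),
        starts=df["start_s"].to_numpy(dtype=float),
        durations=durations,
        n_levels=n_levels,
        dead_time=float(meta.get("dead_time_s", 0.0)),
        total_time=float(durations.sum()),
    )


def read_iv_tsv(path) -> IVDataset:
    return IVDataset(pd.read_csv(path, sep="\t", comment="#"))


def write_iv_tsv(data: IVDataset, path) -> None:
    data.points.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_spans_tsv(path) -> list:
    """Helix-span config: TSV with columns label, chain, first, last."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        (str(r["label"]), str(r["chain"]), int(r["first"]), int(r["last"]))
        for _, r in df.iterrows()
    ]


def read_pore_profile_tsv(path) -> pd.DataFrame:
    """Pore profile: TSV with columns z_A, radius_A (profiler output)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"z_A", "radius_A"}.issubset(df.columns):
        raise ValueError("profile needs columns z_A and radius_A")
    return df
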