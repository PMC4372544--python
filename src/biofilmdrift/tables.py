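"""CSV serialization of trajectories and summaries.

Trajectories are written long-format, one row per recorded state per taxon:
``run,event,taxon,count,rel_abundance`` for the discrete engine and
``run,time,taxon,rel_abundance`` for the continuous one.  Files are plain
RFC-4180 CSV (header row, '.' decimal, UTF-8) and carry no timestamps, so a
rerun with the same seed reproduces them byte for byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import TaxonSet, Trajectory

__all__ = [
    "write_trajectories",
    "read_trajectories",
    "write_summaries",
    "write_absorption_times",
]


def write_trajectories(trajs, path) -> None:
    """Write a batch of same-engine trajectories as one long CSV."""
    trajs = list(trajs)
    frames = [t.to_frame(run=i) for i, t in enumerate(trajs)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path) -> list[Trajectory]:
    """Rebuild trajectories from a CSV written by :func:`write_trajectories`.

    Engine kind is inferred from the index column name (``event`` vs
    ``time``).  Only state data survives the round trip; seeds and
    parameters are stored in the run manifest, not the CSV.
    """
    df = pd.read_csv(path)
    kind = "discrete" if "event" in df.columns else "continuous"
    idx_col = "event" if kind == "discrete" else "time"
    labels = tuple(dict.fromkeys(df["taxon"]))  # keep first-seen order
    taxa = TaxonSet(labels)
    out = []
    for run, grp in df.groupby("run", sort=True):
        value_col = "count" if kind == "discrete" else "rel_abundance"
        wide = grp.pivot(index=idx_col, columns="taxon", values=value_col)
        wide = wide[list(labels)].sort_index()
        out.append(
            Trajectory(
                index=wide.index.to_numpy(),
                values=wide.to_numpy(
                    dtype=np.int64 if kind == "discrete" else float
                ),
                kind=kind,
                taxa=taxa,
                seed=-1,  # unknown after a round trip
                record_every=1,
            )
        )
    return out


def write_summaries(summaries, taxa: TaxonSet, path) -> None:
    """CSV with columns run,taxon,mean,variance,eliminated,elimination_index."""
    from .analysis import summaries_to_frame

    summaries_to_frame(summaries, taxa).to_csv(path, index=False)


def write_absorption_times(rows, path) -> None:
    """CSV with columns alpha_star,m_star,b,expected_time."""
    pd.DataFrame(rows, columns=["alpha_star", "m_star", "b", "expected_time"]).to_csv(
        path, index=False
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
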