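"""Trajectory and results I/O.

Trajectories (decorrelated conformations plus loop snapshots) go into
HDF5 containers with deterministic layout; tabular results go into TSV
files with '#'-prefixed header comments carrying the resolved
parameters and seed.  Contact maps are written both dense and as sparse
(i, j, count) triplets.  All writers are deterministic given identical
inputs, and truncated files are detected through stored record counts.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .equilibration import EquilibrationReport
from .simulate import Ensemble

FORMAT_VERSION = 1


class TrajectoryFormatError(RuntimeError):
    """Unreadable, truncated or incompatibly versioned trajectory file."""


def _dset(group, name, data):
    # track_times=False keeps files byte-identical across runs
    group.create_dataset(name, data=data, track_times=False)


def write_trajectory(path, ens: Ensemble, config: dict | None = None) -> None:
    """Write an :class:`Ensemble` to an HDF5 container."""
    loops_concat = (
        np.concatenate([lp.reshape(-1, 2) for lp in ens.loops])
        if ens.loops
        else np.empty((0, 2), dtype=np.int64)
    )
    offsets = np.zeros(len(ens.loops) + 1, dtype=np.int64)
    if ens.loops:
        offsets[1:] = np.cumsum([lp.shape[0] for lp in ens.loops])
    with h5py.File(path, "w", track_order=True) as fh:
        fh.attrs["format_version"] = FORMAT_VERSION
        fh.attrs["seed"] = ens.seed
        fh.attrs["L"] = np.asarray(ens.L, dtype=np.int64)
        fh.attrs["n_samples"] = ens.n_samples
        fh.attrs["config"] = json.dumps(config or {}, sort_keys=True)
        fh.attrs["meta"] = json.dumps(ens.meta, sort_keys=True, default=float)
        if ens.report is not None:
            fh.attrs["equilibration"] = json.dumps(ens.report.to_dict(), sort_keys=True)
        _dset(fh, "positions", ens.positions.astype(np.int32))
        _dset(fh, "times", ens.times.astype(np.int64))
        _dset(fh, "chain_id", ens.chain_id.astype(np.int32))
        _dset(fh, "loops", loops_concat.astype(np.int64))
        _dset(fh, "loop_offsets", offsets)


def read_trajectory(path) -> Ensemble:
    """Read a trajectory container back into an :class:`Ensemble`."""
    with h5py.File(path, "r") as fh:
        version = int(fh.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise TrajectoryFormatError(
                f"unsupported trajectory format version {version}"
            )
        required = ("positions", "times", "chain_id", "loops", "loop_offsets")
        for name in required:
            if name not in fh:
                raise TrajectoryFormatError(f"missing dataset '{name}'")
        positions = fh["positions"][...]
        times = fh["times"][...]
        n_samples = int(fh.attrs["n_samples"])
        if positions.shape[0] != n_samples or times.shape[0] != n_samples:
            raise TrajectoryFormatError(
                f"truncated trajectory: header announces {n_samples} samples, "
                f"found {positions.shape[0]}"
            )
        offsets = fh["loop_offsets"][...]
        loops_concat = fh["loops"][...]
        if offsets.size != n_samples + 1 or (
            offsets.size and offsets[-1] != loops_concat.shape[0]
        ):
            raise TrajectoryFormatError("truncated loop record")
        loops = [
            loops_concat[offsets[k] : offsets[k + 1]] for k in range(n_samples)
        ]
        report = None
        if "equilibration" in fh.attrs:
            report = EquilibrationReport(**json.loads(fh.attrs["equilibration"]))
        return Ensemble(
            positions=positions,
            times=times,
            chain_id=fh["chain_id"][...],
            L=tuple(int(v) for v in fh.attrs["L"]),
            loops=loops,
            seed=int(fh.attrs["seed"]),
            report=report,
            meta=json.loads(fh.attrs.get("meta", "{}")),
        )


def save_checkpoint(path, state) -> None:
    """Save a resumable snapshot of a :class:`~dynloop.state.SystemState`.

    Kernel RNG streams derive from (seed, call counter), so a resumed
    run continues the exact trajectory of the original.
    """
    np.savez_compressed(
        path,
        pos=state.pos,
        chain_id=state.chain_id,
        L=np.asarray(state.L, dtype=np.int64),
        seed=state.seed,
        mc_time=state.mc_time,
        call_count=state._call_count,
        partners=state.partners,
        pexp=state.pexp,
        pborn=state.pborn,
        ninc=state.ninc,
        counters=state.counters,
    )


def load_checkpoint(path):
    """Restore a :class:`~dynloop.state.SystemState` saved by
    :func:`save_checkpoint`."""
    from .state import SystemState

    with np.load(path) as z:
        st = SystemState(
            z["pos"], z["chain_id"], tuple(int(v) for v in z["L"]),
            seed=int(z["seed"]),
        )
        st.mc_time = int(z["mc_time"])
        st._call_count = int(z["call_count"])
        st.partners[:] = z["partners"]
        st.pexp[:] = z["pexp"]
        st.pborn[:] = z["pborn"]
        st.ninc[:] = z["ninc"]
        st.counters[:] = z["counters"]
    st.validate()
    return st


# ---------------------------------------------------------------------------
# TSV tables


def write_table_tsv(path, columns: dict, header: dict | None = None) -> None:
    """Write named columns as TSV with '#'-commented metadata header."""
    names = list(columns)
    arrays = [np.asarray(columns[k]) for k in names]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("columns must have equal length")
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write(f"# rows: {n}\n")
        fh.write("\t".join(names) + "\n")
        for i in range(n):
            fh.write("\t".join(_fmt(a[i]) for a in arrays) + "\n")


def _fmt(v) -> str:
    if isinstance(v, (np.integer, int)):
        return str(int(v))
    return f"{float(v):.10g}"


def read_table_tsv(path) -> tuple[dict, dict]:
    """Read a TSV table back as (columns, header) dictionaries."""
    header: dict = {}
    rows = []
    names: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if ":" in line:
                    k, v = line[1:].split(":", 1)
                    header[k.strip()] = v.strip()
                continue
            if names is None:
                names = line.split("\t")
            elif line:
                rows.append(line.split("\t"))
    if names is None:
        raise TrajectoryFormatError(f"no table found in {path}")
    if "rows" in header and int(header["rows"]) != len(rows):
        raise TrajectoryFormatError(
            f"truncated table: header announces {header['rows']} rows, "
            f"found {len(rows)}"
        )
    data = np.asarray(rows, dtype=float) if rows else np.empty((0, len(names)))
    return {name: data[:, k] for k, name in enumerate(names)}, header


def write_loop_log_tsv(path, log, header: dict | None = None) -> None:
    """Append-only loop event table (created_at, expires_at, chain?, i, j)."""
    from .loops import loop_log_to_array

    arr = loop_log_to_array(log)
    write_table_tsv(
        path,
        {
            "created_at": arr[:, 0],
            "expires_at": arr[:, 1],
            "i": arr[:, 2],
            "j": arr[:, 3],
        },
        header,
    )


def write_contact_map(path_dense, path_sparse, matrix, header: dict | None = None) -> None:
    """Write a contact map dense (TSV matrix) and sparse (i, j, count)."""
    M = np.asarray(matrix)
    with open(path_dense, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write(f"# shape: {M.shape[0]} {M.shape[1]}\n")
        for row in M:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")
    ii, jj = np.nonzero(np.triu(M))
    write_table_tsv(
        path_sparse,
        {"i": ii, "j": jj, "count": M[ii, jj]},
        header,
    )


def write_xyz(path, positions, chain_id=None, comment: str = "") -> None:
    """Plain-text XYZ export (one frame per conformation) for viewers."""
    p = np.asarray(positions)
    if p.ndim == 2:
        p = p[None]
    chain_id = (
        np.zeros(p.shape[1], dtype=int) if chain_id is None else np.asarray(chain_id)
    )
    with open(path, "w") as fh:
        for frame in p:
            fh.write(f"{frame.shape[0]}\n{comment}\n")
            for (x, y, z), c in zip(frame, chain_id):
                fh.write(f"C{int(c)} {int(x)} {int(y)} {int(z)}\n")
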