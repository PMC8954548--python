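"""Readers and writers for the on-disk formats the pipeline touches:
fast5 (HDF5) raw signal, FASTA references/basecalls and truth-alignment TSV.

Coordinates are 0-based, half-open everywhere; truth ranges are validated to
partition [0, n) at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGT")


class FormatError(ValueError):
    pass


@dataclass
class Fast5Record:
    read_id: str
    signal: np.ndarray
    sampling_rate: float | None = None


def write_fast5(records: list[Fast5Record], path) -> None:
    """Single-read dialect: one group Raw/Reads/Read_<i>/Signal per read
    (one file can still carry several Read_* groups)."""
    with h5py.File(path, "w") as f:
        for i, rec in enumerate(records):
            grp = f.create_group(f"Raw/Reads/Read_{i}")
            grp.attrs["read_id"] = rec.read_id
            grp.create_dataset("Signal", data=np.asarray(rec.signal, dtype=np.float64))


def write_fast5_multi(records: list[Fast5Record], path) -> None:
    """Multi-read dialect: top-level read_<id> groups with Raw/Signal."""
    with h5py.File(path, "w") as f:
        for rec in records:
            grp = f.create_group(f"read_{rec.read_id}")
            grp.attrs["read_id"] = rec.read_id
            grp.create_dataset("Raw/Signal",
                               data=np.asarray(rec.signal, dtype=np.float64))


def _calibrate(signal: np.ndarray, channel_attrs) -> np.ndarray:
    offset = channel_attrs.get("offset")
    rng = channel_attrs.get("range")
    digi = channel_attrs.get("digitisation")
    if offset is None or rng is None or digi is None:
        return np.asarray(signal, dtype=np.float64)
    return (np.asarray(signal, dtype=np.float64) + float(offset)) \
        * float(rng) / float(digi)


def read_fast5(path) -> list[Fast5Record]:
    """Read all records from either fast5 dialect, converting to pA when
    channel calibration metadata is present."""
    if not h5py.is_hdf5(path):
        raise FormatError(f"{path} is not an HDF5 file")
    records: list[Fast5Record] = []
    with h5py.File(path, "r") as f:
        if "Raw" in f and "Reads" in f["Raw"]:  # single-read dialect
            for name, grp in sorted(f["Raw/Reads"].items()):
                if "Signal" not in grp:
                    raise FormatError(f"missing dataset Raw/Reads/{name}/Signal")
                attrs = dict(f["UniqueGlobalKey/channel_id"].attrs) \
                    if "UniqueGlobalKey/channel_id" in f else {}
                rid = grp.attrs.get("read_id", name)
                rid = rid.decode() if isinstance(rid, bytes) else str(rid)
                records.append(Fast5Record(
                    read_id=rid, signal=_calibrate(grp["Signal"][()], attrs),
                    sampling_rate=attrs.get("sampling_rate")))
        else:  # multi-read dialect
            for name in sorted(k for k in f if k.startswith("read_")):
                grp = f[name]
                if "Raw/Signal" not in grp:
                    raise FormatError(f"missing dataset {name}/Raw/Signal")
                attrs = dict(grp["channel_id"].attrs) if "channel_id" in grp else {}
                rid = grp.attrs.get("read_id", name[len("read_"):])
                rid = rid.decode() if isinstance(rid, bytes) else str(rid)
                records.append(Fast5Record(
                    read_id=rid,
                    signal=_calibrate(grp["Raw/Signal"][()], attrs),
                    sampling_rate=attrs.get("sampling_rate")))
    if not records:
        raise FormatError(f"no reads found in {path}")
    return records


def write_fasta(records: dict[str, str], path) -> None:
    ids = list(records)
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sequence ids")
    out = []
    for rid, seq in records.items():
        if not seq:
            raise FormatError(f"empty sequence for id {rid!r}")
        if not set(seq) <= VALID_BASES:
            raise FormatError(f"non-ACGT symbol in sequence {rid!r}")
        out.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(out, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    result: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in result:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        result[rec.id] = str(rec.seq)
    return result


def write_dataset_cache(path, splits: dict, scalers=None) -> None:
    """Persist split sample lists (ragged, stored concatenated with offsets)
    plus scaler parameters to one HDF5 file."""
    import json as _json

    with h5py.File(path, "w") as f:
        if scalers is not None:
            f.attrs["scalers"] = _json.dumps(scalers.to_dict())
        for name, samples in splits.items():
            g = f.create_group(name)
            raw = [s.raw_values for s in samples]
            ev = [s.event_features for s in samples]
            tgt = [np.asarray(s.target_tokens, dtype=np.int64) for s in samples]
            g.create_dataset("raw", data=np.concatenate(raw) if raw else np.zeros(0))
            g.create_dataset("raw_offsets",
                             data=np.cumsum([0] + [len(r) for r in raw]))
            g.create_dataset("events", data=np.concatenate(ev) if ev
                             else np.zeros((0, 5)))
            g.create_dataset("event_offsets",
                             data=np.cumsum([0] + [len(e) for e in ev]))
            g.create_dataset("targets", data=np.concatenate(tgt) if tgt
                             else np.zeros(0, dtype=np.int64))
            g.create_dataset("target_offsets",
                             data=np.cumsum([0] + [len(t) for t in tgt]))
            g.create_dataset("read_ids", data=np.array(
                [s.read_id for s in samples], dtype=h5py.string_dtype()))
            g.create_dataset("raw_starts",
                             data=np.array([s.raw_start for s in samples]))


def read_dataset_cache(path):
    """Inverse of :func:`write_dataset_cache`; returns (splits, scalers)."""
    import json as _json

    from .samples import SampleRecord, ScalerSet

    splits: dict[str, list] = {}
    with h5py.File(path, "r") as f:
        scalers = ScalerSet.from_dict(_json.loads(f.attrs["scalers"])) \
            if "scalers" in f.attrs else None
        for name, g in f.items():
            raw = g["raw"][()]
            ro = g["raw_offsets"][()]
            ev = g["events"][()]
            eo = g["event_offsets"][()]
            tgt = g["targets"][()]
            to = g["target_offsets"][()]
            rids = [r.decode() if isinstance(r, bytes) else str(r)
                    for r in g["read_ids"][()]]
            starts = g["raw_starts"][()]
            samples = [SampleRecord(
                read_id=rids[i],
                raw_values=raw[ro[i]:ro[i + 1]],
                event_features=ev[eo[i]:eo[i + 1]],
                target_tokens=[int(t) for t in tgt[to[i]:to[i + 1]]],
                raw_start=int(starts[i])) for i in range(len(rids))]
            splits[name] = samples
    return splits, scalers


TRUTH_COLUMNS = ["read_id", "base_index", "base", "raw_start", "raw_end"]


@dataclass
class TruthAlignment:
    bases: str
    ranges: np.ndarray  # (m, 2) sorted half-open, partition of [0, n)


def write_truth_tsv(reads, path) -> None:
    """One row per base: read_id, base_index, base, raw_start, raw_end."""
    rows = []
    for read in reads:
        for j, (s, e) in enumerate(read.truth_ranges):
            rows.append((read.read_id, j, read.reference.sequence[j],
                         int(s), int(e)))
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> dict[str, TruthAlignment]:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"truth TSV missing columns: {sorted(missing)}")
    out: dict[str, TruthAlignment] = {}
    for rid, grp in df.groupby("read_id", sort=False):
        grp = grp.sort_values("base_index")
        ranges = grp[["raw_start", "raw_end"]].to_numpy(dtype=np.int64)
        if ranges[0, 0] != 0:
            raise FormatError(
                f"read {rid!r}: truth ranges must start at 0 "
                f"(got {ranges[0, 0]}; 1-based input?)")
        if np.any(ranges[:, 1] <= ranges[:, 0]):
            raise FormatError(f"read {rid!r}: empty or inverted range")
        if np.any(ranges[1:, 0] != ranges[:-1, 1]):
            raise FormatError(
                f"read {rid!r}: ranges must be sorted, disjoint and contiguous")
        out[str(rid)] = TruthAlignment(bases="".join(grp["base"]), ranges=ranges)
    return out
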