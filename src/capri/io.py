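"""Serialization: strategy files, criteria reports, result tables.

A strategy file is a small JSON document carrying the full lookup table as a
hex-encoded bitstring: bit ``k`` (of the little-endian integer the hex string
denotes) is the prescribed action at the history with integer code ``k``
(1 = defect).  The encoding tag ``hex-table-lsb-newest`` records that within
each player's field of the history code, the least significant bit is the
newest round.  Round trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .strategies import DeterministicStrategy

__all__ = ["write_strategy", "read_strategy", "strategy_to_dict", "strategy_from_dict"]

FORMAT_VERSION = 1
_ENCODING = "hex-table-lsb-newest"


def _table_to_hex(table: np.ndarray) -> str:
    bits = int(len(table))
    raw = np.packbits(table.astype(np.uint8), bitorder="little").tobytes()
    value = int.from_bytes(raw, "little")
    width = max(1, bits // 4)
    return format(value, f"0{width}x")


def _hex_to_table(hex_str: str, n_entries: int) -> np.ndarray:
    expected = max(1, n_entries // 4)
    if len(hex_str) != expected:
        raise ValueError(
            f"table field has {len(hex_str)} hex digits, expected {expected}"
        )
    value = int(hex_str, 16)
    if value >> n_entries:
        raise ValueError("table field has bits beyond the declared history space")
    raw = value.to_bytes((n_entries + 7) // 8, "little")
    bits = np.unpackbits(np.frombuffer(raw, dtype=np.uint8), bitorder="little")
    return bits[:n_entries].astype(np.uint8)


def strategy_to_dict(s: DeterministicStrategy) -> dict:
    if s.table is None:
        raise ValueError("only materialized tables are serializable")
    return {
        "format_version": FORMAT_VERSION,
        "n": s.n,
        "m": s.m,
        "name": s.name,
        "encoding": _ENCODING,
        "table": _table_to_hex(s.table),
    }


def strategy_from_dict(d: dict) -> DeterministicStrategy:
    for key in ("format_version", "n", "m", "encoding", "table"):
        if key not in d:
            raise ValueError(f"strategy file missing field {key!r}")
    if d["format_version"] != FORMAT_VERSION:
        raise ValueError(
            f"unsupported strategy format_version {d['format_version']!r}"
        )
    if d["encoding"] != _ENCODING:
        raise ValueError(f"unsupported table encoding {d['encoding']!r}")
    n, m = int(d["n"]), int(d["m"])
    table = _hex_to_table(d["table"], 1 << (n * m))
    return DeterministicStrategy(n, m, table=table, name=d.get("name", ""))


def write_strategy(s: DeterministicStrategy, path) -> None:
    Path(path).write_text(json.dumps(strategy_to_dict(s), indent=1))


def read_strategy(path) -> DeterministicStrategy:
    return strategy_from_dict(json.loads(Path(path).read_text()))
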