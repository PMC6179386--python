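"""Readers and writers for the plain-text formats used throughout the package.

All tabular files are TSV with a header row. Protein identifiers are opaque
strings; no identifier-system mapping is performed. Writers emit rows in a
deterministic (sorted) order so that repeated runs with the same seed produce
byte-identical files.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

EDGE_COLUMNS = ["protein_a", "protein_b", "class", "evidence", "condition", "weight"]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return format(value, ".10g")
    return str(value)


def write_edge_list(net: nx.Graph, path, extra_attrs: Iterable[str] = ()) -> None:
    """Write an interaction network as an edge-list TSV.

    Columns: protein_a, protein_b, class, evidence (comma-joined), condition,
    weight, plus any ``extra_attrs`` (e.g. r, p, q for co-abundance edges).
    """
    extra = list(extra_attrs)
    rows = []
    for u, v, data in net.edges(data=True):
        a, b = sorted((u, v))
        row = [
            a,
            b,
            data.get("kind", "ppi"),
            ",".join(sorted(data.get("evidence", ()) or ())),
            data.get("condition") or "",
            _fmt(float(data.get("weight", 1.0))),
        ]
        row.extend(_fmt(data.get(attr)) for attr in extra)
        rows.append(row)
    rows.sort()
    with open(path, "w") as fh:
        fh.write("\t".join(EDGE_COLUMNS + extra) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_edge_list(path) -> nx.Graph:
    """Read an edge-list TSV written by :func:`write_edge_list`.

    Also accepts minimal two-column files (protein_a, protein_b); missing
    columns default to class=ppi, empty evidence, weight 1.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    g = nx.Graph()
    for d in df.to_dict(orient="records"):
        a, b = d["protein_a"], d["protein_b"]
        evidence = frozenset(x for x in d.get("evidence", "").split(",") if x)
        attrs = {
            "kind": d.get("class", "ppi") or "ppi",
            "evidence": evidence,
            "condition": d.get("condition") or None,
            "weight": float(d.get("weight") or 1.0),
        }
        for key in ("r", "p", "q"):
            if d.get(key):
                attrs[key] = float(d[key])
        g.add_edge(a, b, **attrs)
    return g


def time_column(hours: float) -> str:
    return f"t{hours:g}"


def write_abundance(frame: pd.DataFrame, path) -> None:
    """Write a proteins x time-points abundance table (columns t0, t8, ...)."""
    out = frame.copy()
    out.columns = [time_column(c) for c in frame.columns]
    out = out.sort_index()
    out.to_csv(path, sep="\t", index_label="protein", float_format="%.10g")


def read_abundance(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="protein")
    frame.columns = [float(c.lstrip("t")) for c in frame.columns]
    frame.index.name = None
    return frame.astype(float)


def write_seed_list(members: Iterable[str], path, weights: Mapping[str, float] | None = None) -> None:
    with open(path, "w") as fh:
        for m in sorted(members):
            if weights is not None:
                fh.write(f"{m}\t{_fmt(float(weights.get(m, 1.0)))}\n")
            else:
                fh.write(m + "\n")


def read_seed_list(path) -> tuple[list[str], dict[str, float]]:
    members, weights = [], {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            members.append(parts[0])
            weights[parts[0]] = float(parts[1]) if len(parts) > 1 else 1.0
    return members, weights


def write_gmt(sets: Mapping[str, Iterable[str]], path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            desc = (descriptions or {}).get(name, "na")
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_gmt(path) -> dict[str, frozenset]:
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = frozenset(p for p in parts[2:] if p)
    return sets


def write_fold_changes(frame: pd.DataFrame, path) -> None:
    frame.sort_index().to_csv(path, sep="\t", index_label="protein", float_format="%.10g")


def read_fold_changes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="protein")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    try:
        import numpy as np

        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
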