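"""Table and network readers/writers with schema validation.

All tabular interchange is TSV with a declared header; reports and truth
objects are JSON.  Networks round-trip through a signed edge-list TSV and
can additionally be exported as SIF or GraphML for viewers.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .network import RegulatoryNetwork

__all__ = [
    "SchemaError",
    "SCHEMAS",
    "read_table",
    "write_table",
    "read_network",
    "write_network",
    "write_sif",
    "write_graphml",
    "write_report",
]


class SchemaError(ValueError):
    """Input table does not match its declared schema."""


#: Declared column sets per table kind.
SCHEMAS: dict[str, list[str]] = {
    "reporter": ["promoter", "driver", "set", "replicate", "rlu"],
    "qpcr": ["target", "genotype", "bio_rep", "tech_rep", "ct", "copies"],
    "standards": ["copies", "ct"],
    "edges": ["regulator", "target", "sign", "weight"],
    "effects": ["promoter", "driver", "effect_log10", "se", "p", "q", "call"],
    "copies": ["target", "genotype", "bio_rep", "copies", "log2_copies"],
    "genotype_effects": [
        "target", "genotype", "effect_log2", "se", "p", "q", "call",
        "regulatory_activity",
    ],
    "contributions": ["target", "factor", "estimate", "se", "p", "q"],
}

_NUMERIC = {
    "rlu", "ct", "copies", "weight", "effect_log10", "se", "p", "q",
    "log2_copies", "effect_log2", "regulatory_activity", "estimate",
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a TSV and validate it against a named schema.

    Missing columns raise :class:`SchemaError` naming them; extra columns
    are kept.  A header-only file yields an empty, correctly-typed table.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise SchemaError(f"{path}: empty file (expected header {SCHEMAS[schema]})")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing} for schema {schema!r} "
            f"(found {list(df.columns)})"
        )
    for col in df.columns:
        if col in _NUMERIC:
            try:
                df[col] = pd.to_numeric(df[col])
            except (TypeError, ValueError) as exc:
                bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
                line = int(bad[0]) + 2 if len(bad) else "?"
                raise SchemaError(
                    f"{path}: column {col!r} not numeric (line {line})"
                ) from exc
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_network(path: str | Path) -> RegulatoryNetwork:
    return RegulatoryNetwork.from_frame(read_table(path, "edges"))


def write_network(net: RegulatoryNetwork, path: str | Path) -> Path:
    return write_table(net.to_frame(), path)


def write_sif(net: RegulatoryNetwork, path: str | Path) -> Path:
    """Simple interaction format: regulator <activates|represses> target."""
    path = Path(path)
    lines = [
        f"{e.regulator}\t{'activates' if e.sign > 0 else 'represses'}\t{e.target}"
        for e in net.edges
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_graphml(net: RegulatoryNetwork, path: str | Path) -> Path:
    g = net.to_digraph(include_auto=True)
    nx.write_graphml(g, path)
    return Path(path)


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path
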