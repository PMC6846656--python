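"""Light-weight column schemas for the TSV outputs.

Every table the pipeline writes carries a header; ``validate_tsv``
checks the expected columns are present with parseable dtypes, so
downstream steps can fail fast on malformed hand-offs.
"""

from __future__ import annotations

import pandas as pd

SCHEMAS: dict[str, dict[str, str]] = {
    "mutation_table": {
        "strand": "str", "pos": "int", "ref": "str", "denominator": "int",
        "n_A": "int", "n_C": "int", "n_G": "int", "n_T": "int", "rate": "float",
    },
    "clone_calls": {"uid": "str", "strand": "str", "pos": "int", "ref": "str", "alt": "str"},
    "truth": {"clone_id": "int", "strand": "str", "pos": "int", "coord": "int",
              "ref": "str", "alt": "str"},
    "spectrum": {"coord": "int", "pos": "int", "strand": "str", "motif": "str",
                 "region": "str", "numerator": "int", "denominator": "int",
                 "rate": "float", "freq_pct": "float"},
    "region_summary": {"region": "str", "mutations": "int", "percent": "float"},
    "manifest": {"group": "str", "strand": "str", "replicate": "int",
                 "denominator": "int", "numerator": "int"},
    "cd": {"d": "int", "C": "float", "n_pairs": "int"},
    "clone_histogram": {"n_mutations": "int", "clones": "int", "fraction": "float"},
}

_CASTS = {"int": "int64", "float": "float64", "str": "object"}


class SchemaError(ValueError):
    pass


def validate_frame(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    if kind not in SCHEMAS:
        raise SchemaError(f"unknown schema {kind!r}")
    schema = SCHEMAS[kind]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind}: missing columns {missing}")
    for col, typ in schema.items():
        if len(df) == 0:
            continue
        try:
            df[col].astype(_CASTS[typ])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{kind}: column {col!r} not parseable as {typ}: {exc}") from exc
    return df


def validate_tsv(path, kind: str) -> pd.DataFrame:
    return validate_frame(pd.read_csv(path, sep="\t"), kind)
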