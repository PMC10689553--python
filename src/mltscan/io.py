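"""Readers and writers for the tabular formats the scan touches.

Abundance tables are CSV/TSV/XLSX with a header row and sample IDs, in either
orientation (samples in rows, or MetaboLights-style metabolite-assignment
files with metabolites in rows and samples in columns).  Non-numeric cells
become missing markers; ``<LOQ`` cells are mapped to the metabolite's known
LOQ so the encoder left-censors them.  The canonical in-memory form is a
samples x metabolites :class:`pandas.DataFrame` with unique sample IDs.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "na", "nan", "n/a", "null"}
_LOQ_TOKEN = re.compile(r"^<\s*loq$", re.IGNORECASE)


def _read_table(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt"):
        return pd.read_csv(path, sep="\t", **kwargs)
    if suffix == ".csv":
        return pd.read_csv(path, **kwargs)
    if suffix in (".xlsx", ".xls"):
        return pd.read_excel(path, **kwargs)
    raise ValueError(f"unsupported table format {suffix!r} for {path}")


def _coerce_numeric(df: pd.DataFrame, loq_map: Optional[Dict[str, float]]) -> pd.DataFrame:
    """Numeric coercion with '<LOQ' substitution and a logged missing count."""
    out = {}
    n_coerced = 0
    for col in df.columns:
        s = df[col]
        if s.dtype == object:
            s = s.astype(str).str.strip()
            is_loq = s.str.match(_LOQ_TOKEN)
            if is_loq.any():
                if loq_map is None or col not in loq_map:
                    raise ValueError(
                        f"column {col!r} contains '<LOQ' cells but no LOQ is known; "
                        "supply it via the LOQ map (e.g. --loq-map)"
                    )
                s = s.mask(is_loq, str(loq_map[col]))
            s = s.mask(s.str.lower().isin(_MISSING_TOKENS), np.nan)
        coerced = pd.to_numeric(s, errors="coerce").astype(float)
        n_coerced += int((coerced.isna() & df[col].notna() & ~pd.isna(s)).sum())
        out[col] = coerced
    if n_coerced:
        logger.info("coerced %d non-numeric cells to missing", n_coerced)
    return pd.DataFrame(out, index=df.index)


def read_abundance(
    path,
    orientation: str = "samples_in_rows",
    loq_map: Optional[Dict[str, float]] = None,
) -> pd.DataFrame:
    """Read an abundance table into canonical samples x metabolites orientation."""
    if orientation not in ("samples_in_rows", "metabolites_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    header = _read_table(path, header=None, nrows=1).iloc[0, 1:].tolist()
    dup_raw = sorted({str(h) for h in header if header.count(h) > 1})
    df = _read_table(path, index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty table")
    if orientation == "metabolites_in_rows":
        df = df.T
    dup = df.columns[df.columns.duplicated()].unique().tolist()
    if orientation == "samples_in_rows":
        dup = sorted(set(dup) | set(dup_raw))  # pandas mangles duplicate headers
    if dup:
        raise ValueError(f"{path}: duplicate metabolite names {dup}")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs")
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return _coerce_numeric(df, loq_map)


def read_metabolights_assignment(
    path,
    name_column: str = "metabolite_identification",
    sample_pattern: Optional[str] = None,
) -> pd.DataFrame:
    """Read a MetaboLights metabolite-assignment TSV (``m_*.tsv``).

    These files keep one metabolite per row; intensity columns are selected
    by ``sample_pattern`` (a regex) when given, otherwise every column that
    parses fully numeric is taken as a sample.
    """
    df = _read_table(path)
    if name_column not in df.columns:
        raise ValueError(
            f"{path}: no column {name_column!r}; available: {list(df.columns)[:20]}"
        )
    names = df[name_column].astype(str)
    if sample_pattern is not None:
        rex = re.compile(sample_pattern)
        sample_cols = [c for c in df.columns if rex.search(str(c))]
    else:
        sample_cols = [
            c
            for c in df.columns
            if c != name_column and pd.to_numeric(df[c], errors="coerce").notna().all()
        ]
    if not sample_cols:
        raise ValueError(f"{path}: no intensity columns matched")
    out = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    out.index = names
    if out.index.duplicated().any():
        dup = out.index[out.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate metabolite names {dup[:10]}")
    out = out.T
    out.index = out.index.astype(str)
    out.index.name = "sample_id"
    out.columns.name = None
    return out


def read_metadata(
    path,
    exposure_name: str,
    covariate_names: Sequence[str] = (),
) -> pd.DataFrame:
    """Read the per-sample metadata table with typed, validated columns."""
    df = _read_table(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    wanted = [exposure_name, *covariate_names]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        import difflib

        hints = {
            c: difflib.get_close_matches(c, [str(x) for x in df.columns], n=3)
            for c in missing
        }
        raise ValueError(f"{path}: missing columns {missing}; close matches: {hints}")
    out = df[wanted].apply(pd.to_numeric, errors="coerce")
    if out[exposure_name].isna().all():
        raise ValueError(f"{path}: exposure column {exposure_name!r} is not numeric")
    ex = out[exposure_name].dropna()
    logger.info(
        "exposure %s: n=%d, range [%g, %g]", exposure_name, ex.size, ex.min(), ex.max()
    )
    return out


def write_abundance(df: pd.DataFrame, path) -> None:
    """Canonical CSV/TSV dialect: UTF-8, decimal point, empty cell = missing."""
    sep = "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, na_rep="")


def parse_loq_map(items: Sequence[str]) -> Dict[str, float]:
    """Parse ``NAME=VALUE`` strings (CLI) into a LOQ map."""
    out: Dict[str, float] = {}
    for item in items:
        if "=" not in item:
            raise ValueError(f"LOQ entry {item!r} is not of the form NAME=VALUE")
        name, _, value = item.partition("=")
        out[name.strip()] = float(value)
    return out


def load_loq_map(path) -> Dict[str, float]:
    """Load a LOQ map from YAML (mapping) or two-column CSV/TSV."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of metabolite -> LOQ")
        return {str(k): float(v) for k, v in data.items()}
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need two columns (metabolite, loq)")
    return {str(k): float(v) for k, v in zip(df.iloc[:, 0], df.iloc[:, 1])}
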