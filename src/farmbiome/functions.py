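"""Taxon-to-function aggregation (FAPROTAX-style).

The aggregation engine consumes a user-supplied two-column genus ->
function table (e.g. an export from the FAPROTAX database, which is not
redistributed here) and produces per-status percentage abundance for each
functional group. A genus mapped to k functions contributes its abundance
to all k before normalisation — the usual semantics of function tables —
and each status column is normalised to 100% over the function-assigned
abundance mass. Functions observed in exactly one status are flagged
exclusive to it.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["load_function_map", "function_profile"]


def load_function_map(path: str | Path) -> dict[str, set[str]]:
    """Parse a two-column TSV (``genus``, ``function``) into a mapping.

    One genus-function pair per row; duplicates collapse; keys are
    whitespace-trimmed and case-preserving. Malformed rows are reported
    with their line numbers.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file (expected a header row)")
    header = [c.strip() for c in lines[0].split("\t")]
    if header[:2] != ["genus", "function"]:
        raise ValueError(
            f"{path}:1: header must be 'genus<TAB>function', got {lines[0]!r}"
        )
    mapping: dict[str, set[str]] = {}
    bad: list[int] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = [c.strip() for c in line.split("\t")]
        if len(parts) != 2 or not parts[0] or not parts[1]:
            bad.append(lineno)
            continue
        mapping.setdefault(parts[0], set()).add(parts[1])
    if bad:
        raise ValueError(f"{path}: malformed rows at lines {bad}")
    return mapping


def function_profile(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    function_map: dict[str, set[str]],
) -> pd.DataFrame:
    """Per-status percentage abundance by functional group.

    For each status, per-sample relative abundances are averaged within
    the group, summed into every function each genus maps to, and
    normalised so the status column sums to 100%. Returns a DataFrame
    with columns ``function``, ``HHS_pct``, ``LHS_pct``, ``exclusive_to``
    sorted by descending HHS percentage.
    """
    mapped = [g for g in counts.columns if g in function_map]
    if not mapped:
        raise ValueError("no genus in the table is present in the function map")
    status = metadata.set_index("sample_id")["status"].loc[counts.index]
    rel = counts.div(counts.sum(axis=1), axis=0)
    group_mean = rel.groupby(status.values).mean()  # status x genera

    functions = sorted({f for g in mapped for f in function_map[g]})
    rows = []
    totals = {}
    raw = pd.DataFrame(0.0, index=functions, columns=group_mean.index)
    for g in mapped:
        for f in function_map[g]:
            raw.loc[f] += group_mean[g]
    for st in raw.columns:
        totals[st] = raw[st].sum()
    for f in functions:
        pct = {
            st: (100.0 * raw.loc[f, st] / totals[st] if totals[st] > 0 else 0.0)
            for st in raw.columns
        }
        hhs, lhs = pct.get("HHS", 0.0), pct.get("LHS", 0.0)
        if hhs > 0 and lhs == 0:
            exclusive = "HHS"
        elif lhs > 0 and hhs == 0:
            exclusive = "LHS"
        else:
            exclusive = ""
        rows.append(
            {
                "function": f,
                "HHS_pct": hhs,
                "LHS_pct": lhs,
                "exclusive_to": exclusive,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        "HHS_pct", ascending=False, kind="stable", ignore_index=True
    )
    return out
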