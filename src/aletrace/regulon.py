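"""Transcriptome post-processing: fold changes, induction filter,
regulator attribution.

Works on FPKM expression tables with replicate measurements per
(gene, strain).  Fold change of a mutant against the parent is computed
on replicate means (matching the "average of independent experiments"
convention), genes induced by strictly more than a threshold fold are
selected, and the fraction of induced genes controlled by each
transcriptional regulator is computed against a user-supplied
regulator → target map (e.g. exported from a regulation database).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "read_expression",
    "read_regulator_map",
    "compute_fold_changes",
    "select_induced",
    "regulator_fractions",
]

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_THRESHOLD = 1.5


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a long-form FPKM table: columns gene, strain, replicate, fpkm."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "strain", "replicate", "fpkm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing expression columns {sorted(missing)}")
    if (df["fpkm"] < 0).any():
        raise ValueError(f"{path}: negative FPKM values")
    return df


def read_regulator_map(path: str | Path) -> dict[str, set[str]]:
    """Read a regulator → target map: TSV with columns regulator, target."""
    df = pd.read_csv(path, sep="\t")
    if not {"regulator", "target"} <= set(df.columns):
        raise ValueError(f"{path}: need columns 'regulator' and 'target'")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.regulator), set()).add(str(row.target))
    empty = [r for r, t in out.items() if not t]
    if empty:
        raise ValueError(f"regulators with empty target sets: {empty}")
    return out


def compute_fold_changes(
    table: pd.DataFrame,
    parent_strain: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Fold change of every mutant strain vs the parent, per gene.

    FC = (mean mutant FPKM + eps) / (mean parent FPKM + eps), replicate
    means first.  With eps = 0, genes whose parent mean is 0 are
    undefined and excluded with a warning.  Returns genes × mutants.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    means = table.groupby(["gene", "strain"])["fpkm"].mean().unstack("strain")
    if parent_strain not in means.columns:
        raise ValueError(f"parent strain {parent_strain!r} not in expression table")
    parent = means[parent_strain]
    mutants = [c for c in means.columns if c != parent_strain]
    if pseudocount == 0:
        undefined = parent[parent == 0].index
        if len(undefined):
            warnings.warn(
                f"{len(undefined)} genes have parent mean FPKM 0 with "
                "pseudocount 0; excluded as undefined"
            )
            means = means.drop(index=undefined)
            parent = parent.drop(index=undefined)
    fc = (means[mutants] + pseudocount).div(parent + pseudocount, axis=0)
    fc.columns.name = "strain"
    return fc


def select_induced(
    fold_changes: pd.Series | Mapping[str, float],
    threshold: float = DEFAULT_THRESHOLD,
) -> set[str]:
    """Genes induced by strictly more than ``threshold``-fold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    s = pd.Series(fold_changes, dtype=float)
    return set(s.index[s > threshold])


def regulator_fractions(
    induced: set[str], regulator_map: Mapping[str, set[str]]
) -> pd.Series:
    """Percentage of induced genes controlled by each regulator.

    100 × |targets ∩ induced| / |induced| per regulator; regulators may
    share targets, so the percentages need not sum to 100.
    """
    if not induced:
        raise ValueError(
            "induced gene set is empty — nothing to attribute; lower the "
            "threshold or check the fold-change inputs"
        )
    return pd.Series(
        {
            reg: 100.0 * len(set(targets) & induced) / len(induced)
            for reg, targets in regulator_map.items()
        }
    ).sort_values(ascending=False)
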