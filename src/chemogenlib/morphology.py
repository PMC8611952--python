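"""Cell Painting profile processing.

Image-based profiling yields, per compound and replicate, a wide vector
of morphological features measured on three cellular compartments (whole
cell, cytoplasm, nucleus).  Processing follows the standard recipe:
average the replicates per compound, then — independently within each
compartment — drop constant features and greedily remove features highly
correlated (|Pearson r| >= 0.95 by default) with one already kept,
scanning in the input column order.  Profiled compounds are finally
linked to the bioactivity network by exact InChIKey match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import ConfigError, PipelineConfig

COMPARTMENTS = ("cell", "cyto", "nucl")

#: feature-name prefixes mapped to compartments (CellProfiler naming)
_PREFIXES = {
    "cells": "cell",
    "cell": "cell",
    "cytoplasm": "cyto",
    "cyto": "cyto",
    "nuclei": "nucl",
    "nucleus": "nucl",
    "nucl": "nucl",
}


def compartment_of(feature: str) -> str:
    """Compartment tag from a ``Compartment_Category_Name`` feature name."""
    prefix = feature.split("_", 1)[0].lower()
    try:
        return _PREFIXES[prefix]
    except KeyError:
        raise ValueError(f"feature {feature!r} has no recognised compartment prefix")


def aggregate_replicates(
    table: pd.DataFrame,
    compound_col: str = "compound_id",
    replicate_col: str | None = "replicate",
) -> pd.DataFrame:
    """Average replicate rows per compound.

    Missing values are ignored in the mean; a feature missing in every
    replicate of a compound stays missing.  Returns one row per compound
    indexed by compound id, feature columns in input order.
    """
    feature_cols = [
        c for c in table.columns if c not in {compound_col, replicate_col}
    ]
    grouped = table.groupby(compound_col, sort=True)[feature_cols].mean()
    return grouped


def select_features(
    matrix: pd.DataFrame,
    cfg: PipelineConfig,
) -> dict[str, list[str]]:
    """Per-compartment feature filtering; returns survivors per compartment.

    Within each compartment independently: features with zero standard
    deviation are dropped, then features are scanned in input column
    order and kept iff their absolute Pearson correlation with every
    feature already kept stays below ``cfg.corr_threshold``.  The
    surviving set therefore satisfies pairwise |r| < threshold and
    sd > 0.  The result depends on column order (greedy keep-first) but
    not on row order.
    """
    if len(matrix) < 2:
        raise ConfigError("need at least 2 compounds to compute correlations")
    survivors: dict[str, list[str]] = {c: [] for c in COMPARTMENTS}
    kept_values: dict[str, list[np.ndarray]] = {c: [] for c in COMPARTMENTS}
    for feature in matrix.columns:
        comp = compartment_of(feature)
        x = matrix[feature].to_numpy(dtype=float)
        sd = np.nanstd(x)
        if not sd > 0:
            continue
        redundant = False
        for y in kept_values[comp]:
            r = _pearson(x, y)
            if abs(r) >= cfg.corr_threshold:
                redundant = True
                break
        if not redundant:
            survivors[comp].append(feature)
            kept_values[comp].append(x)
    return survivors


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 2:
        return 0.0
    xs, ys = x[mask], y[mask]
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    denom = np.sqrt((xs * xs).sum() * (ys * ys).sum())
    if denom == 0:
        return 0.0
    return float((xs * ys).sum() / denom)


def filtered_matrix(matrix: pd.DataFrame, survivors: Mapping[str, list[str]]) -> pd.DataFrame:
    """Restrict the averaged matrix to surviving features (input order)."""
    keep = [f for f in matrix.columns if f in {s for v in survivors.values() for s in v}]
    return matrix[keep]


@dataclass
class ProfileLink:
    """Outcome of matching profiled compounds to bioactive molecules."""

    matched: dict[str, str]  # profile compound id -> molecule id
    unmatched_profiles: list[str]
    unmatched_molecules: list[str]

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def link_profiles(
    profile_inchikeys: Mapping[str, str],
    molecule_inchikeys: Mapping[str, str],
) -> ProfileLink:
    """Match profiled compounds to network molecules by full InChIKey.

    Both mappings go id -> 27-character InChIKey; matching is exact
    string equality on the full key (stereochemistry-sensitive).
    """
    by_key: dict[str, str] = {}
    for mol_id, key in molecule_inchikeys.items():
        by_key.setdefault(key, mol_id)
    matched = {}
    unmatched_profiles = []
    for comp_id in sorted(profile_inchikeys):
        key = profile_inchikeys[comp_id]
        if key in by_key:
            matched[comp_id] = by_key[key]
        else:
            unmatched_profiles.append(comp_id)
    matched_mols = set(matched.values())
    unmatched_molecules = sorted(
        m for m in molecule_inchikeys if m not in matched_mols
    )
    return ProfileLink(matched, unmatched_profiles, unmatched_molecules)
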