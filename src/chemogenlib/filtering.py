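"""High-confidence bioactivity selection and promiscuity pruning.

A molecule-protein pair enters the network only when supported by at
least one binding-assay record with Ki or IC50 strictly below the potency
threshold (1 uM by default), curation confidence 9, and a human, rat or
mouse target.  Species-specific targets are collapsed onto their
species-agnostic protein entry before pairing, so an ortholog measured in
two species yields a single pair.  Scaffolds hitting more than the
allowed number of protein entries are discarded as promiscuous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .config import PipelineConfig
from .records import ActivityRecord, DataIntegrityError


@dataclass(frozen=True)
class BioactivePair:
    """A retained molecule-protein link with its best qualifying potency."""

    molecule_id: str
    ui_id: str
    best_value_nM: float


def record_qualifies(r: ActivityRecord, cfg: PipelineConfig) -> bool:
    """Whether a single record passes all five activity filters."""
    return (
        r.measure in cfg.allowed_measures
        and r.assay_type == cfg.required_assay_type
        and r.confidence == cfg.required_confidence
        and r.species in cfg.allowed_species
        and r.value_nM < cfg.potency_threshold_nM  # strictly below 1 uM
    )


def filter_bioactive(
    records: Iterable[ActivityRecord],
    target_to_ui: Mapping[str, str],
    cfg: PipelineConfig,
) -> set[BioactivePair]:
    """Reduce raw records to deduplicated bioactive molecule-protein pairs.

    Multiple qualifying records for the same (molecule, protein entry)
    collapse to a single pair carrying the minimum (most potent) value;
    records whose target has no protein-entry mapping are ignored.
    """
    best: dict[tuple[str, str], float] = {}
    for r in records:
        if not record_qualifies(r, cfg):
            continue
        ui = target_to_ui.get(r.target_id)
        if ui is None:
            continue
        key = (r.molecule_id, ui)
        if key not in best or r.value_nM < best[key]:
            best[key] = r.value_nM
    return {
        BioactivePair(molecule_id=m, ui_id=u, best_value_nM=v)
        for (m, u), v in best.items()
    }


def scaffold_target_map(
    pairs: Iterable[BioactivePair],
    molecule_scaffolds: Mapping[str, str],
) -> dict[str, set[str]]:
    """scaffold -> set of protein entries hit by its molecules.

    ``molecule_scaffolds`` maps molecule ids to their selection-level
    scaffold; molecules without one (single-ring frameworks) contribute
    nothing here but remain available for coverage completion.
    """
    out: dict[str, set[str]] = {}
    for p in pairs:
        scaffold = molecule_scaffolds.get(p.molecule_id)
        if scaffold is None:
            continue
        out.setdefault(scaffold, set()).add(p.ui_id)
    return out


def promiscuity_prune(
    scaffold_targets: Mapping[str, set[str]],
    cfg: PipelineConfig,
) -> set[str]:
    """Scaffold ids surviving the promiscuity cut (<= max targets)."""
    survivors = set()
    for scaffold, targets in scaffold_targets.items():
        if not targets:
            raise DataIntegrityError(f"scaffold {scaffold!r} has an empty target set")
        if len(targets) <= cfg.max_targets_per_scaffold:
            survivors.add(scaffold)
    return survivors


def pruning_report(
    scaffold_targets: Mapping[str, set[str]],
    survivors: set[str],
) -> "pd.DataFrame":
    """Per-scaffold pruning outcome (scaffold_id, n_targets, kept)."""
    import pandas as pd

    rows = [
        {"scaffold_id": s, "n_targets": len(t), "kept": s in survivors}
        for s, t in sorted(scaffold_targets.items())
    ]
    return pd.DataFrame(rows, columns=["scaffold_id", "n_targets", "kept"])
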