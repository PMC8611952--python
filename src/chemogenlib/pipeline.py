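"""End-to-end library construction.

Stage order: activity filtering -> scaffold decomposition at the
selection level -> promiscuity pruning -> protein-class restriction ->
binary profile matrix -> hierarchical clustering and representative
scaffolds -> candidate pool extraction -> genetic-algorithm Pareto
selection -> final-subset choice -> coverage completion -> exports.
Every stage's record counts are accumulated in a run manifest whose
internal identities (pruned + retained = generated, and so on) are
checked before it is written.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .clustering import build_matrix, hcluster
from .config import ConfigError, PipelineConfig
from .enrichment import enrich_library, results_table
from .filtering import (
    BioactivePair,
    filter_bioactive,
    promiscuity_prune,
    pruning_report,
    scaffold_target_map,
)
from .graph import GraphBundle, export_graph
from .morphology import aggregate_replicates, link_profiles, select_features
from .pareto import complete_coverage, ga_select
from .records import (
    ActivityRecord,
    AnnotationMap,
    DataIntegrityError,
    ProteinClassNode,
    TargetEntity,
    map_targets_to_ui,
)
from .scaffolds import level_scaffold_map


@dataclass
class RunManifest:
    """Provenance and per-stage bookkeeping of one pipeline run.

    With the same config, seed and inputs, the manifest is sufficient to
    reproduce the run exactly.
    """

    config: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    chosen_objectives: dict = field(default_factory=dict)
    uncoverable_ui: list = field(default_factory=list)
    rng_seed: int = 0

    def check_identities(self) -> None:
        c = self.counts
        if c.get("scaffolds_pruned", 0) + c.get("scaffolds_retained", 0) != c.get(
            "scaffolds_generated", 0
        ):
            raise DataIntegrityError("manifest identity pruned + retained != generated")
        if c.get("library_size", 0) != c.get("subset_size", 0) + c.get(
            "completion_additions", 0
        ):
            raise DataIntegrityError(
                "manifest identity subset + additions != library size"
            )

    def to_json(self, path: str | Path) -> None:
        self.check_identities()
        payload = {
            "config": self.config,
            "input_digests": self.input_digests,
            "counts": self.counts,
            "chosen_objectives": self.chosen_objectives,
            "uncoverable_ui": self.uncoverable_ui,
            "rng_seed": self.rng_seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class PipelineResult:
    library: list[str]
    additions: list[str]
    uncoverable_ui: list[str]
    manifest: RunManifest
    bundle: GraphBundle
    chosen_objectives: tuple
    representatives: list[str]
    pairs: set[BioactivePair]
    molecule_scaffolds: dict[str, str]


def restrict_protein_classes(
    ui_class_map: Mapping[str, Sequence[str]],
    classes: Sequence[ProteinClassNode],
) -> tuple[set[str], set[str]]:
    """Split protein entries by the level-1 class restriction.

    Returns (classified, unclassified): entries linked to at least one
    level-1 class node stay on the main selection path; the rest — the
    proteins the classification schema never attached to a family — are
    routed to the coverage-completion pool.
    """
    level1 = {c.class_id for c in classes if c.level == 1}
    classified = set()
    unclassified = set()
    for ui, class_ids in ui_class_map.items():
        if any(cid in level1 for cid in class_ids):
            classified.add(ui)
        else:
            unclassified.add(ui)
    return classified, unclassified


def ui_class_map_from_targets(targets: Sequence[TargetEntity]) -> dict[str, list[str]]:
    out: dict[str, set[str]] = {}
    for t in targets:
        out.setdefault(t.ui_id, set()).update(t.protein_class_ids)
    return {u: sorted(v) for u, v in out.items()}


def run_pipeline(
    records: Sequence[ActivityRecord],
    targets: Sequence[TargetEntity],
    classes: Sequence[ProteinClassNode],
    cfg: PipelineConfig,
    annotations: Sequence[AnnotationMap] | None = None,
    morphology: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the complete selection workflow on in-memory inputs.

    When ``out_dir`` is given, every stage output (pairs, scaffold table,
    pruning report, matrix sidecars, cluster assignment, fronts, final
    library, enrichment tables, graph exports, manifest) is persisted
    there as plain text.
    """
    manifest = RunManifest(config=cfg.to_dict(), rng_seed=cfg.rng_seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # 1. activity filtering onto species-agnostic protein entries
    target_to_ui = map_targets_to_ui(targets)
    pairs = filter_bioactive(records, target_to_ui, cfg)
    if not pairs:
        raise DataIntegrityError("no bioactive pairs survive filtering")
    molecule_targets: dict[str, set[str]] = {}
    for p in pairs:
        molecule_targets.setdefault(p.molecule_id, set()).add(p.ui_id)
    bioactive_molecules = sorted(molecule_targets)
    all_ui = sorted({p.ui_id for p in pairs})
    manifest.counts["records_in"] = len(records)
    manifest.counts["pairs_retained"] = len(pairs)
    manifest.counts["molecules_bioactive"] = len(bioactive_molecules)
    manifest.counts["ui_bioactive"] = len(all_ui)

    # 2. scaffold decomposition at the selection level
    molecule_smiles = {}
    for r in records:
        molecule_smiles.setdefault(r.molecule_id, r.smiles)
    molecule_scaffolds = level_scaffold_map(
        {m: molecule_smiles[m] for m in bioactive_molecules}, cfg.scaffold_level
    )
    scaffold_targets = scaffold_target_map(pairs, molecule_scaffolds)
    manifest.counts["scaffolds_generated"] = len(scaffold_targets)

    # 3. promiscuity pruning
    survivors = promiscuity_prune(scaffold_targets, cfg)
    manifest.counts["scaffolds_retained"] = len(survivors)
    manifest.counts["scaffolds_pruned"] = len(scaffold_targets) - len(survivors)

    # 4. protein-class restriction: entries without a level-1 class go to
    # the completion pool
    ui_classes = ui_class_map_from_targets(targets)
    classified, unclassified = restrict_protein_classes(
        {u: ui_classes.get(u, []) for u in all_ui}, classes
    )
    manifest.counts["ui_classified"] = len(classified)
    manifest.counts["ui_unclassified"] = len(unclassified)
    main_pairs = {p for p in pairs if p.ui_id in classified}

    # 5. binary scaffold-by-protein matrix (pruned scaffolds absent)
    matrix = build_matrix(main_pairs, molecule_scaffolds, survivors)

    # 6. clustering and representative scaffolds
    scaffold_molecule_counts: dict[str, int] = {}
    for m, s in molecule_scaffolds.items():
        scaffold_molecule_counts[s] = scaffold_molecule_counts.get(s, 0) + 1
    k = min(cfg.n_clusters, len(matrix.row_ids))
    assignment = hcluster(matrix, k, cfg, scaffold_molecule_counts)
    representatives = sorted(assignment.representatives.values())
    manifest.counts["clusters"] = assignment.n_clusters

    # 7. candidate pool: all bioactive molecules carrying a selected scaffold
    pool = sorted(
        m for m in bioactive_molecules if molecule_scaffolds.get(m) in set(representatives)
    )
    manifest.counts["pool_size"] = len(pool)
    if cfg.subset_size > len(pool):
        raise ConfigError(
            f"subset_size={cfg.subset_size} exceeds the candidate pool ({len(pool)})"
        )

    # 8-9. genetic algorithm and final-subset choice
    result = ga_select(pool, molecule_targets, molecule_scaffolds, representatives, cfg)
    chosen = result.chosen
    manifest.counts["subset_size"] = len(chosen.molecule_ids)
    manifest.chosen_objectives = {
        "ui_coverage": chosen.objectives.ui_coverage,
        "scaffold_count": chosen.objectives.scaffold_count,
        "mean_hits": chosen.objectives.mean_hits,
    }

    # 10. coverage completion over every bioactive protein entry
    molecule_inchikeys = {}
    for r in records:
        if r.inchikey:
            molecule_inchikeys.setdefault(r.molecule_id, r.inchikey)
    library, additions, uncoverable = complete_coverage(
        chosen.molecule_ids,
        bioactive_molecules,
        all_ui,
        molecule_targets,
        molecule_scaffolds,
        scaffold_molecule_counts,
        molecule_inchikeys,
    )
    manifest.counts["completion_additions"] = len(additions)
    manifest.counts["library_size"] = len(library)
    manifest.uncoverable_ui = uncoverable
    manifest.check_identities()

    # graph bundle over the final library
    bundle = build_graph_bundle(
        library,
        pairs,
        molecule_scaffolds,
        molecule_smiles,
        molecule_inchikeys,
        targets,
        classes,
        annotations or [],
        morphology,
        cfg,
    )

    enrichment_results = None
    if annotations:
        lib_targets = {m: molecule_targets[m] for m in library if m in molecule_targets}
        enrichment_results = enrich_library(lib_targets, list(annotations), cfg)

    if out is not None:
        _persist(
            out,
            manifest,
            pairs,
            molecule_scaffolds,
            library,
            additions,
            molecule_smiles,
            molecule_inchikeys,
            result,
            matrix,
            assignment,
            enrichment_results,
            bundle,
            scaffold_targets,
            survivors,
        )

    return PipelineResult(
        library=library,
        additions=additions,
        uncoverable_ui=uncoverable,
        manifest=manifest,
        bundle=bundle,
        chosen_objectives=chosen.objectives.as_tuple(),
        representatives=representatives,
        pairs=pairs,
        molecule_scaffolds=molecule_scaffolds,
    )


def build_graph_bundle(
    library: Sequence[str],
    pairs: Iterable[BioactivePair],
    molecule_scaffolds: Mapping[str, str],
    molecule_smiles: Mapping[str, str],
    molecule_inchikeys: Mapping[str, str],
    targets: Sequence[TargetEntity],
    classes: Sequence[ProteinClassNode],
    annotations: Sequence[AnnotationMap],
    morphology: pd.DataFrame | None,
    cfg: PipelineConfig,
) -> GraphBundle:
    """Assemble the property graph for the final library.

    Nodes: molecules, their scaffolds, targets, protein entries, protein
    classes, annotation terms and (when profiles are given) per-compartment
    morphology descriptors; edges follow the fixed relation vocabulary.
    """
    bundle = GraphBundle()
    lib_set = set(library)
    mol_nodes = {}
    for m in sorted(lib_set):
        mol_nodes[m] = bundle.add_node(
            "Molecule",
            m,
            smiles=molecule_smiles.get(m, ""),
            inchikey=molecule_inchikeys.get(m, ""),
        )
    ui_nodes: dict[str, str] = {}
    target_nodes: dict[str, str] = {}
    used_targets = [t for t in targets if t.species in cfg.allowed_species]
    lib_uis = {p.ui_id for p in pairs if p.molecule_id in lib_set}
    for t in used_targets:
        if t.ui_id not in lib_uis:
            continue
        if t.target_id not in target_nodes:
            target_nodes[t.target_id] = bundle.add_node(
                "Target", t.target_id, name=t.name, species=t.species
            )
        if t.ui_id not in ui_nodes:
            ui_nodes[t.ui_id] = bundle.add_node("UniprotInter", t.ui_id)
        bundle.add_edge(target_nodes[t.target_id], ui_nodes[t.ui_id], "isUI")
    class_nodes: dict[str, str] = {}
    for c in classes:
        class_nodes[c.class_id] = bundle.add_node(
            "ProteinClass", c.class_id, name=c.name, level=c.level
        )
    for c in classes:
        if c.parent_id and c.parent_id in class_nodes:
            bundle.add_edge(class_nodes[c.class_id], class_nodes[c.parent_id], "memberOf")
    linked_classes = set()
    for t in used_targets:
        if t.ui_id in ui_nodes:
            for cid in t.protein_class_ids:
                if cid in class_nodes and (t.ui_id, cid) not in linked_classes:
                    bundle.add_edge(ui_nodes[t.ui_id], class_nodes[cid], "memberOf")
                    linked_classes.add((t.ui_id, cid))
    scaffold_nodes: dict[str, str] = {}
    for m in sorted(lib_set):
        s = molecule_scaffolds.get(m)
        if s is None:
            continue
        if s not in scaffold_nodes:
            scaffold_nodes[s] = bundle.add_node("Scaffold", s, level=cfg.scaffold_level)
        bundle.add_edge(mol_nodes[m], scaffold_nodes[s], "hasScaffold")
    for p in sorted(pairs, key=lambda p: (p.molecule_id, p.ui_id)):
        if p.molecule_id in lib_set and p.ui_id in ui_nodes:
            bundle.add_edge(
                mol_nodes[p.molecule_id],
                ui_nodes[p.ui_id],
                "actifConf9",
                best_value_nM=p.best_value_nM,
            )
    for ann in annotations:
        term_node = bundle.add_node(ann.namespace, ann.term_id, name=ann.term_name)
        for ui in sorted(ann.members):
            if ui in ui_nodes:
                bundle.add_edge(ui_nodes[ui], term_node, "actIn")
    if morphology is not None and "inchikey" in morphology.columns:
        key_to_mol = {}
        for m in sorted(lib_set):
            k = molecule_inchikeys.get(m)
            if k:
                key_to_mol.setdefault(k, m)
        desc_labels = {"cell": "CellDesc", "cyto": "CytoDesc", "nucl": "NuclDesc"}
        seen_profiles = set()
        for _, row in morphology.iterrows():
            key = row["inchikey"]
            if key in key_to_mol and key not in seen_profiles:
                seen_profiles.add(key)
                m = key_to_mol[key]
                for comp, label in desc_labels.items():
                    desc = bundle.add_node(label, f"{key}_{comp}")
                    bundle.add_edge(mol_nodes[m], desc, "hasMorph")
    return bundle


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _persist(
    out: Path,
    manifest: RunManifest,
    pairs,
    molecule_scaffolds,
    library,
    additions,
    molecule_smiles,
    molecule_inchikeys,
    ga_result,
    matrix,
    assignment,
    enrichment_results,
    bundle,
    scaffold_targets,
    survivors,
) -> None:
    pair_rows = [
        {"molecule_id": p.molecule_id, "ui_id": p.ui_id, "best_value_nM": p.best_value_nM}
        for p in pairs
    ]
    pair_rows.sort(key=lambda r: (r["molecule_id"], r["ui_id"]))
    pd.DataFrame(pair_rows).to_csv(out / "pairs.csv", index=False)
    pruning_report(scaffold_targets, survivors).to_csv(out / "pruning.csv", index=False)
    with open(out / "matrix_rows.txt", "w") as fh:
        fh.write("\n".join(matrix.row_ids) + "\n")
    with open(out / "matrix_cols.txt", "w") as fh:
        fh.write("\n".join(matrix.col_ids) + "\n")
    _write_mtx(out / "matrix.mtx", matrix.values)
    pd.DataFrame(
        [
            {
                "scaffold_id": sid,
                "cluster": lab,
                "representative": assignment.representatives[lab] == sid,
            }
            for sid, lab in sorted(assignment.labels.items())
        ]
    ).to_csv(out / "clusters.csv", index=False)
    pd.DataFrame(
        [
            {
                "molecule_id": m,
                "inchikey": molecule_inchikeys.get(m, ""),
                "smiles": molecule_smiles.get(m, ""),
                "scaffold": molecule_scaffolds.get(m, ""),
                "completion_addition": m in set(additions),
            }
            for m in library
        ]
    ).to_csv(out / "library.csv", index=False)
    fronts_payload = [
        {
            "rank": front.rank,
            "subsets": [
                {
                    "creation_index": s.creation_index,
                    "objectives": list(s.objectives.as_tuple()),
                }
                for s in front.subsets
            ],
        }
        for front in ga_result.fronts
    ]
    with open(out / "fronts.json", "w") as fh:
        json.dump(fronts_payload, fh, indent=1)
    pd.DataFrame(ga_result.history).to_csv(out / "objective_trace.csv", index=False)
    if enrichment_results is not None:
        results_table(enrichment_results).to_csv(out / "enrichment.csv", index=False)
    export_graph(bundle, out / "graph", format="graphml")
    export_graph(bundle, out / "graph_csv", format="neo4j_csv")
    manifest.to_json(out / "manifest.json")


def _write_mtx(path: Path, values) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(str(path), csr_matrix(values.astype(int)))


def process_morphology(
    morphology: pd.DataFrame,
    cfg: PipelineConfig,
    molecule_inchikeys: Mapping[str, str],
) -> dict:
    """Replicate averaging, feature filtering and network linking.

    Returns the averaged matrix, survivors per compartment, and the
    InChIKey match against the bioactive molecule set.
    """
    id_cols = [c for c in ("compound_id", "inchikey", "replicate") if c in morphology.columns]
    feature_cols = [c for c in morphology.columns if c not in id_cols]
    averaged = aggregate_replicates(
        morphology[["compound_id"] + feature_cols], compound_col="compound_id"
    )
    survivors = select_features(averaged, cfg)
    profile_keys = (
        morphology.drop_duplicates("compound_id").set_index("compound_id")["inchikey"].to_dict()
        if "inchikey" in morphology.columns
        else {}
    )
    link = link_profiles(profile_keys, dict(molecule_inchikeys))
    return {"averaged": averaged, "survivors": survivors, "link": link}
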