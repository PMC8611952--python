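"""Seeded synthetic inputs with recorded ground truth.

Desk-scale stand-ins for the real inputs (a ChEMBL-style bioactivity
dump, target metadata, protein-class tree, term annotations, and a Cell
Painting profile table): compounds are built by decorating known
multi-ring template scaffolds, so every molecule's scaffold chain is
known a priori; potencies are log-normal around per-family means with a
configurable fraction of records violating each activity filter;
annotation files carry planted enriched terms; and the morphology table
plants constant and collinear features with known survivors.  Everything
is reconstructible from (seed, config), and each generator records its
ground truth so downstream stages can be checked exactly.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from rdkit import Chem

from .records import ActivityRecord, AnnotationMap, ProteinClassNode, TargetEntity
from .scaffolds import canonical_smiles

# three-ring family templates: a central ring carrying two flanking ring
# systems, so every family has a known 3-ring framework whose level-2
# scaffold (one ring pruned) is still family-specific
_MIDDLE = ["c1cc({b})ccc1{c}", "c1nc({b})ccc1{c}", "C1CN({b})CCN1{c}"]
_FLANK = [
    "c{d}ccccc{d}",
    "c{d}ccncc{d}",
    "c{d}cccs{d}",
    "c{d}ccco{d}",
    "C{d}CCCCC{d}",
    "C{d}CCNCC{d}",
    "c{d}ncccn{d}",
    "c{d}ccc{e}ccccc{e}c{d}",
]
_LINKERS = ["", "C", "CC", "O", "CN"]

#: saturated side chains used to decorate templates (never add rings or
#: exocyclic double bonds, so the planted framework is preserved)
_SIDE_CHAINS = ["C", "CC", "CCC", "CO", "CCO", "CN", "CCN", "OC", "N", "F", "Cl"]

PROTEIN_FAMILIES = (
    "Enzyme",
    "MembraneReceptor",
    "IonChannel",
    "Transporter",
    "TranscriptionFactor",
    "Epigenetic",
    "AuxiliaryTransportProtein",
)


def family_templates(n_families: int) -> list[str]:
    """Deterministic list of distinct 3-ring template scaffolds.

    Templates are accepted only when both the framework and its level-2
    scaffold (one ring pruned by the decomposition cascade) are new, so
    every family occupies its own row of the scaffold-target matrix.
    """
    from .scaffolds import remove_one_ring

    seen_l1: set[str] = set()
    seen_l2: set[str] = set()
    out: list[str] = []
    # vary both flanking rings fastest so early families differ everywhere
    n_f = len(_FLANK)
    combos = []
    for i in range(n_f * n_f):
        b, c = _FLANK[i % n_f], _FLANK[(i // n_f + i) % n_f]
        combos.append((b, c))
    for lb in _LINKERS:
        for lc in _LINKERS:
            for middle in _MIDDLE:
                for b, c in combos:
                    b_part = lb + b.format(d=2, e=3)
                    c_part = lc + c.format(d=4, e=5)
                    smi = middle.format(b=b_part, c=c_part)
                    mol = Chem.MolFromSmiles(smi)
                    if mol is None:
                        continue
                    canon = canonical_smiles(smi)
                    if canon in seen_l1:
                        continue
                    try:
                        level2 = remove_one_ring(canon)
                    except Exception:
                        continue
                    if level2 is None or level2 in seen_l2:
                        continue
                    seen_l1.add(canon)
                    seen_l2.add(level2)
                    out.append(canon)
                    if len(out) == n_families:
                        return out
    raise ValueError(
        f"only {len(out)} distinct templates available, {n_families} requested"
    )


def _decorate(template: str, chain: str, position: int, rng: np.random.Generator) -> str:
    """Attach a saturated side chain to a ring CH of the template."""
    mol = Chem.MolFromSmiles(template)
    sites = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetTotalNumHs() > 0 and a.GetSymbol() == "C"
    ]
    if not sites:
        return template
    site = sites[position % len(sites)]
    frag = Chem.MolFromSmiles(chain)
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


@dataclass
class SyntheticConfig:
    """Shape and noise parameters of the synthetic study.

    Defaults describe a desk-scale study: 60 scaffold families of 6
    decorated analogues over an 80-protein target space, with 10% of
    activity records violating each filter in turn.
    """

    n_families: int = 60
    molecules_per_family: int = 6
    n_ui: int = 80
    max_targets_per_family: int = 3
    n_promiscuous_families: int = 3
    promiscuous_targets: int = 8
    records_per_pair: int = 2
    violation_fraction: float = 0.10
    log_potency_mean_nM: float = 100.0
    log_potency_sigma: float = 1.0
    unclassified_ui_fraction: float = 0.10
    n_terms_per_namespace: int = 12
    n_planted_terms: int = 4
    term_size_range: tuple[int, int] = (2, 6)
    n_morph_compounds: int = 40
    n_shared_inchikeys: int = 7
    n_independent_features: int = 10
    n_constant_features: int = 2
    n_collinear_features: int = 3
    max_replicates: int = 8
    seed: int = 0


@dataclass
class SyntheticGroundTruth:
    """Everything the generators planted, for exact downstream checks."""

    seed: int
    templates: dict[str, str] = field(default_factory=dict)  # family -> level-1 scaffold
    family_members: dict[str, list[str]] = field(default_factory=dict)
    molecule_smiles: dict[str, str] = field(default_factory=dict)
    molecule_inchikey: dict[str, str] = field(default_factory=dict)
    family_targets: dict[str, list[str]] = field(default_factory=dict)
    promiscuous_families: list[str] = field(default_factory=list)
    expected_pairs: list[list] = field(default_factory=list)  # [mol, ui, best_value]
    ui_ids: list[str] = field(default_factory=list)
    ui_species: dict[str, list[str]] = field(default_factory=dict)
    unclassified_uis: list[str] = field(default_factory=list)
    planted_terms: list[list] = field(default_factory=list)  # [molecule, term_id]
    expected_morph_survivors: dict[str, list[str]] = field(default_factory=dict)
    shared_inchikeys: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticGroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def gen_compound_library(cfg: SyntheticConfig, rng: np.random.Generator, truth: SyntheticGroundTruth) -> None:
    """Decorated analogue series with known level-1 scaffolds."""
    templates = family_templates(cfg.n_families)
    for f, template in enumerate(templates):
        family = f"FAM{f:03d}"
        truth.templates[family] = template
        members = []
        for d in range(cfg.molecules_per_family):
            mol_id = f"MOL{f:03d}_{d}"
            chain = _SIDE_CHAINS[int(rng.integers(len(_SIDE_CHAINS)))]
            smiles = _decorate(template, chain, position=d, rng=rng)
            truth.molecule_smiles[mol_id] = smiles
            truth.molecule_inchikey[mol_id] = Chem.MolToInchiKey(
                Chem.MolFromSmiles(smiles)
            )
            members.append(mol_id)
        truth.family_members[family] = members


def gen_target_space(cfg: SyntheticConfig, rng: np.random.Generator, truth: SyntheticGroundTruth) -> tuple[list[TargetEntity], list[ProteinClassNode]]:
    """Protein entries (with species variants) and a 7-family class tree."""
    truth.ui_ids = [f"UI{u:03d}" for u in range(cfg.n_ui)]
    n_unclassified = int(round(cfg.unclassified_ui_fraction * cfg.n_ui))
    unclassified = set(
        rng.choice(cfg.n_ui, size=n_unclassified, replace=False).tolist()
    )
    truth.unclassified_uis = [f"UI{u:03d}" for u in sorted(unclassified)]

    classes: list[ProteinClassNode] = []
    for fam_idx, family in enumerate(PROTEIN_FAMILIES):
        root = f"PC_{family}"
        classes.append(ProteinClassNode(class_id=root, name=family, level=2, parent_id=None))
        for leaf in range(3):
            classes.append(
                ProteinClassNode(
                    class_id=f"{root}_L1_{leaf}",
                    name=f"{family} subfamily {leaf}",
                    level=1,
                    parent_id=root,
                )
            )
    level1_ids = [c.class_id for c in classes if c.level == 1]

    targets: list[TargetEntity] = []
    for u in range(cfg.n_ui):
        ui = f"UI{u:03d}"
        if u in unclassified:
            class_ids: tuple[str, ...] = ()
        else:
            class_ids = (level1_ids[int(rng.integers(len(level1_ids)))],)
        species_list = ["human"] + (["rat"] if rng.random() < 0.5 else []) + (
            ["mouse"] if rng.random() < 0.3 else []
        )
        truth.ui_species[ui] = species_list
        for sp in species_list + ["other"]:
            targets.append(
                TargetEntity(
                    target_id=f"{ui}_{sp.upper()}",
                    name=f"protein {ui} ({sp})",
                    species=sp,
                    ui_id=ui,
                    protein_class_ids=class_ids,
                )
            )
    return targets, classes


_VIOLATIONS = ("assay_type", "confidence", "measure", "species", "potency")


def gen_activity_table(
    cfg: SyntheticConfig, rng: np.random.Generator, truth: SyntheticGroundTruth
) -> list[ActivityRecord]:
    """Activity records with per-predicate planted violations.

    Each record is either fully qualifying or carries exactly one planted
    violation; the expected retained pair set (with its best value) is
    recorded in the truth object.  Two boundary records are always
    planted: one at exactly the 1000 nM threshold (must be excluded) and
    one just below it (must be retained).
    """
    families = sorted(truth.family_members)
    n_promiscuous = min(cfg.n_promiscuous_families, max(len(families) - 1, 0))
    promiscuous = sorted(
        rng.choice(len(families), size=n_promiscuous, replace=False).tolist()
    )
    truth.promiscuous_families = [families[i] for i in promiscuous]

    records: list[ActivityRecord] = []
    best: dict[tuple[str, str], float] = {}
    for f_idx, family in enumerate(families):
        if family in truth.promiscuous_families:
            n_targets = cfg.promiscuous_targets
        else:
            n_targets = int(rng.integers(1, cfg.max_targets_per_family + 1))
        target_uis = sorted(
            rng.choice(cfg.n_ui, size=n_targets, replace=False).tolist()
        )
        truth.family_targets[family] = [f"UI{u:03d}" for u in target_uis]
        fam_mean = float(
            np.exp(rng.normal(np.log(cfg.log_potency_mean_nM), 0.5))
        )
        for mol_id in truth.family_members[family]:
            for ui in truth.family_targets[family]:
                for _ in range(cfg.records_per_pair):
                    value = float(np.exp(rng.normal(np.log(fam_mean), cfg.log_potency_sigma)))
                    # draw from the species the target table actually carries
                    available = truth.ui_species[ui]
                    species = available[int(rng.integers(len(available)))]
                    measure = ["Ki", "IC50"][int(rng.integers(2))]
                    assay_type, confidence = "B", 9
                    violation = None
                    if rng.random() < cfg.violation_fraction:
                        violation = _VIOLATIONS[int(rng.integers(len(_VIOLATIONS)))]
                        if violation == "assay_type":
                            assay_type = ["A", "F", "U"][int(rng.integers(3))]
                        elif violation == "confidence":
                            confidence = int(rng.integers(0, 9))
                        elif violation == "measure":
                            measure = ["EC50", "other"][int(rng.integers(2))]
                        elif violation == "species":
                            species = "other"
                        elif violation == "potency":
                            value = float(rng.uniform(1000.0, 100000.0))
                    records.append(
                        ActivityRecord(
                            molecule_id=mol_id,
                            smiles=truth.molecule_smiles[mol_id],
                            inchikey=truth.molecule_inchikey[mol_id],
                            target_id=f"{ui}_{species.upper()}",
                            species=species,
                            assay_type=assay_type,
                            measure=measure,
                            value_nM=value,
                            confidence=confidence,
                        )
                    )
                    clean = violation is None and value < 1000.0
                    if clean:
                        key = (mol_id, ui)
                        if key not in best or value < best[key]:
                            best[key] = value

    # explicit strict-boundary records on a dedicated pair: a protein the
    # first family does not otherwise touch, so the 999 nM record is the
    # pair's only qualifying evidence
    family = families[0]
    mol_id = truth.family_members[family][0]
    linked = set(truth.family_targets[family])
    ui = next(u for u in (f"UI{i:03d}" for i in range(cfg.n_ui)) if u not in linked)
    for value in (1000.0, 999.0):
        records.append(
            ActivityRecord(
                molecule_id=mol_id,
                smiles=truth.molecule_smiles[mol_id],
                inchikey=truth.molecule_inchikey[mol_id],
                target_id=f"{ui}_HUMAN",
                species="human",
                assay_type="B",
                measure="Ki",
                value_nM=value,
                confidence=9,
            )
        )
    best[(mol_id, ui)] = 999.0

    truth.expected_pairs = [[m, u, v] for (m, u), v in sorted(best.items())]
    return records


def gen_annotations(
    cfg: SyntheticConfig, rng: np.random.Generator, truth: SyntheticGroundTruth
) -> list[AnnotationMap]:
    """Random term memberships plus planted co-annotated terms.

    Planted terms contain exactly two targets of a chosen multi-target
    molecule and nothing else, so in the sparse universe they come out
    significant at the default cutoff.
    """
    namespaces = {"GO": "GO:{:07d}", "KEGG": "KEGG:hsa{:05d}", "DO": "DOID:{:04d}"}
    annotations: list[AnnotationMap] = []
    for ns, pattern in namespaces.items():
        for t in range(cfg.n_terms_per_namespace):
            lo, hi = cfg.term_size_range
            size = int(rng.integers(lo, hi + 1))
            members = rng.choice(cfg.n_ui, size=min(size, cfg.n_ui), replace=False)
            term_id = pattern.format(t + 1)
            annotations.append(
                AnnotationMap(
                    term_id=term_id,
                    term_name=f"synthetic {ns} term {t + 1}",
                    namespace=ns,
                    members=frozenset(f"UI{u:03d}" for u in members),
                )
            )
    # plant terms on molecules known to hit >= 2 proteins
    multi = [
        (family, targets)
        for family, targets in sorted(truth.family_targets.items())
        if len(targets) >= 2 and family not in truth.promiscuous_families
    ]
    for p in range(min(cfg.n_planted_terms, len(multi))):
        family, targets = multi[p]
        molecule = truth.family_members[family][0]
        term_id = f"GO:{9000000 + p}"
        annotations.append(
            AnnotationMap(
                term_id=term_id,
                term_name=f"planted term {p}",
                namespace="GO",
                members=frozenset(targets[:2]),
            )
        )
        truth.planted_terms.append([molecule, term_id])
    return annotations


def gen_morphology(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    truth: SyntheticGroundTruth,
) -> pd.DataFrame:
    """Replicated Cell Painting-style table with planted feature structure.

    Per compartment: ``n_independent_features`` Gaussian features,
    ``n_constant_features`` constants, and ``n_collinear_features`` noisy
    copies of the first independent feature (|r| > 0.95).  Expected
    survivors are the independents plus the first collinear copy.
    """
    prefixes = {"cell": "Cells", "cyto": "Cytoplasm", "nucl": "Nuclei"}
    shared = sorted(truth.molecule_inchikey)[: cfg.n_shared_inchikeys]
    truth.shared_inchikeys = [truth.molecule_inchikey[m] for m in shared]
    n_foreign = cfg.n_morph_compounds - len(shared)
    letters = np.array(list(string.ascii_uppercase))
    foreign_keys = []
    for _ in range(n_foreign):
        a = "".join(rng.choice(letters, size=14))
        b = "".join(rng.choice(letters, size=10))
        foreign_keys.append(f"{a}-{b}-N")
    inchikeys = truth.shared_inchikeys + foreign_keys
    compound_ids = [f"BRD{i:04d}" for i in range(len(inchikeys))]

    columns: dict[str, np.ndarray] = {}
    constant_names: set[str] = set()
    n_comp = len(compound_ids)
    for comp, prefix in prefixes.items():
        expected = []
        base: list[np.ndarray] = []
        for i in range(cfg.n_independent_features):
            name = f"{prefix}_Intensity_F{i:02d}"
            x = rng.normal(0.0, 1.0, size=n_comp)
            columns[name] = x
            base.append(x)
            expected.append(name)
        for i in range(cfg.n_constant_features):
            name = f"{prefix}_AreaShape_Const{i}"
            columns[name] = np.full(n_comp, float(i))
            constant_names.add(name)
        # collinear group: noisy copies of a fresh latent vector, so the
        # members correlate with each other (r >> 0.95) but not with the
        # independents; only the first-seen member survives
        latent = rng.normal(0.0, 1.0, size=n_comp)
        for i in range(cfg.n_collinear_features):
            name = f"{prefix}_Texture_Derived{i}"
            columns[name] = latent + rng.normal(0.0, 0.05, size=n_comp)
            if i == 0:
                expected.append(name)
        truth.expected_morph_survivors[comp] = expected

    rows = []
    for c_idx, comp_id in enumerate(compound_ids):
        n_rep = int(rng.integers(1, cfg.max_replicates + 1))
        for rep in range(n_rep):
            row = {"compound_id": comp_id, "inchikey": inchikeys[c_idx], "replicate": rep + 1}
            for name, mean_values in columns.items():
                noise = 0.0 if name in constant_names else rng.normal(0.0, 0.01)
                row[name] = float(mean_values[c_idx] + noise)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SyntheticBundle:
    """In-memory synthetic study: all inputs plus the ground truth."""

    truth: SyntheticGroundTruth
    records: list[ActivityRecord]
    targets: list[TargetEntity]
    classes: list[ProteinClassNode]
    annotations: list[AnnotationMap]
    morphology: pd.DataFrame
    config: SyntheticConfig


def generate_bundle(seed: int, **overrides) -> SyntheticBundle:
    """Generate the full synthetic study for one seed."""
    cfg = SyntheticConfig(seed=seed, **overrides)
    rng = np.random.default_rng(seed)
    truth = SyntheticGroundTruth(seed=seed)
    gen_compound_library(cfg, rng, truth)
    targets, classes = gen_target_space(cfg, rng, truth)
    records = gen_activity_table(cfg, rng, truth)
    annotations = gen_annotations(cfg, rng, truth)
    morphology = gen_morphology(cfg, rng, truth)
    return SyntheticBundle(truth, records, targets, classes, annotations, morphology, cfg)


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as the flat files the CLI pipeline ingests."""
    from .records import write_activity_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["activity"] = out_dir / "activity.csv"
    write_activity_table(bundle.records, paths["activity"])

    paths["targets"] = out_dir / "targets.csv"
    pd.DataFrame(
        [
            {
                "target_id": t.target_id,
                "name": t.name,
                "species": t.species,
                "ui_id": t.ui_id,
                "protein_class_ids": ";".join(t.protein_class_ids),
            }
            for t in bundle.targets
        ]
    ).to_csv(paths["targets"], index=False)

    paths["classes"] = out_dir / "protein_classes.csv"
    pd.DataFrame(
        [
            {
                "class_id": c.class_id,
                "name": c.name,
                "level": c.level,
                "parent_id": c.parent_id or "",
            }
            for c in bundle.classes
        ]
    ).to_csv(paths["classes"], index=False)

    paths["annotations"] = out_dir / "annotations.tsv"
    with open(paths["annotations"], "w") as fh:
        for ann in bundle.annotations:
            for ui in sorted(ann.members):
                fh.write(f"{ann.term_id}\t{ui}\n")
    paths["term_names"] = out_dir / "term_names.tsv"
    with open(paths["term_names"], "w") as fh:
        for ann in bundle.annotations:
            fh.write(f"{ann.term_id}\t{ann.term_name}\n")

    paths["morphology"] = out_dir / "morphology.csv"
    bundle.morphology.to_csv(paths["morphology"], index=False)

    paths["structures"] = out_dir / "structures.smi"
    with open(paths["structures"], "w") as fh:
        for mol_id, smi in sorted(bundle.truth.molecule_smiles.items()):
            fh.write(f"{smi}\t{mol_id}\n")

    paths["truth"] = out_dir / "truth.json"
    bundle.truth.to_json(paths["truth"])
    return paths


def planted_optimum_pool(
    seed: int,
    n_specialists: int = 50,
    uis_per_specialist: int = 2,
    pool_size: int = 300,
) -> dict:
    """Abstract candidate pool with a known perfect-coverage subset.

    ``n_specialists`` profile classes each cover ``uis_per_specialist``
    unique protein entries; the pool is padded to ``pool_size`` with
    redundant copies of the class profiles, spread uniformly.  Any subset
    of ``n_specialists`` molecules containing one member of every class
    achieves full coverage; anything else covers strictly less.
    """
    rng = np.random.default_rng(seed)
    n_ui = n_specialists * uis_per_specialist
    ui_ids = [f"UI{u:03d}" for u in range(n_ui)]
    molecule_targets: dict[str, set[str]] = {}
    molecule_scaffolds: dict[str, str] = {}
    class_of: dict[str, int] = {}
    pool: list[str] = []
    for m in range(pool_size):
        klass = m % n_specialists
        mol_id = f"P{m:04d}"
        targets = {
            ui_ids[klass * uis_per_specialist + j] for j in range(uis_per_specialist)
        }
        molecule_targets[mol_id] = targets
        molecule_scaffolds[mol_id] = f"SCAF{klass:03d}"
        class_of[mol_id] = klass
        pool.append(mol_id)
    order = rng.permutation(pool_size)
    pool = [pool[i] for i in order]
    return {
        "pool": pool,
        "ui_ids": ui_ids,
        "molecule_targets": molecule_targets,
        "molecule_scaffolds": molecule_scaffolds,
        "representative_scaffolds": sorted(set(molecule_scaffolds.values())),
        "class_of": class_of,
        "n_classes": n_specialists,
    }
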