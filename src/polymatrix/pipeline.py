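"""End-to-end pipeline orchestration on synthetic inputs.

``run_pipeline`` wires the stages together at desk scale: simulate
clusters, families and traits; build the clade-specific substitution
matrix; assign orthologs; prune paralogs; assemble, filter and export the
supermatrix; fit ER/ARD Mk models and reconstruct ancestral states. The
returned manifest records per-stage input/output counts, mirroring the
kind of bookkeeping a methods section reports (clusters kept, groups
pruned, groups eligible, matrix statistics, the AICc table).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from . import mkasr, orthology, paralogs, simulate, submat
from . import supermatrix as sm

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and scales in one place.

    The filtering defaults are the study's stated cutoffs; the synthetic
    problem sizes are desk-scale stand-ins for inputs the study obtained
    from external databases.
    """

    seed: int = 0
    # study cutoffs
    min_identity: float = 0.70
    cluster_threshold: float = 0.90
    evalue: float = 1e-5
    quartile: float = 0.25
    occupancy: float = 0.75
    min_col_taxa: int = 4
    sig_threshold: float = 2.0
    support_cutoff: float = 0.0
    root_prior: tuple[float, float] = (0.5, 0.5)
    # synthetic problem sizes
    n_taxa: int = 36
    n_matrix_clusters: int = 12
    cluster_size: int = 6
    cluster_length: int = 240
    cluster_identity: float = 0.92
    n_groups: int = 6
    seq_taxa: int = 8  # taxa carried through the sequence stages
    dup_rate: float = 0.15
    loss_rate: float = 0.05
    unknown_fraction: float = 11.0 / 36.0
    trait_rate: float = 0.5
    # stage toggles
    stages: tuple[str, ...] = (
        "simulate", "build-matrix", "assign", "prune", "supermatrix", "asr"
    )
    out_dir: str | None = None

    def validate(self) -> None:
        for name, lo, hi in (
            ("min_identity", 0, 1), ("quartile", 0, 1), ("occupancy", 0, 1),
            ("unknown_fraction", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.evalue <= 0:
            raise ValueError("evalue must be > 0")
        if self.min_col_taxa < 1:
            raise ValueError("min_col_taxa must be >= 1")
        unknown = set(self.stages) - {
            "simulate", "build-matrix", "assign", "prune", "supermatrix", "asr"
        }
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class RunManifest:
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, **counts) -> None:
        self.stages[stage] = counts

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"config": self.config, "stages": self.stages},
                          indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in order on synthetic inputs."""
    config.validate()
    manifest = RunManifest(config=asdict(config))
    if not config.stages:
        return manifest
    rng = np.random.default_rng(config.seed)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- simulate -----------------------------------------------------
    species_tree = simulate.simulate_species_tree(config.n_taxa, seed=config.seed)
    seq_taxa = sorted(t.label for t in species_tree.taxon_namespace)[: config.seq_taxa]
    seq_tree = species_tree.extract_tree_with_taxa_labels(seq_taxa)

    clusters = []
    families = []
    if "simulate" in config.stages:
        for k in range(config.n_matrix_clusters):
            clusters.append(
                simulate.simulate_cluster(
                    config.cluster_size, config.cluster_length,
                    config.cluster_identity, seed=int(rng.integers(2**31)),
                )
            )
        for g in range(config.n_groups):
            families.append(
                simulate.simulate_gene_family(
                    seq_tree, config.dup_rate, config.loss_rate,
                    seed=int(rng.integers(2**31)),
                )
            )
        manifest.record(
            "simulate",
            n_clusters=len(clusters),
            n_families=len(families),
            n_taxa=config.n_taxa,
            tree_digest=_digest(pio.write_newick(species_tree)),
        )

    # --- build-matrix -------------------------------------------------
    matrix = None
    if "build-matrix" in config.stages:
        curated = submat.curate_clusters(clusters, min_identity=config.min_identity)
        if not curated:
            raise RuntimeError("build-matrix: no clusters survive curation")
        matrix = submat.build_matrix_pipeline(
            curated, clustering_threshold=config.cluster_threshold
        )
        manifest.record(
            "build-matrix",
            clusters_in=len(clusters),
            clusters_kept=len(curated),
            n_blocks=matrix.metadata.get("n_blocks"),
            expected_score=matrix.expected_score(),
        )
        if out_dir:
            ext, scores = submat.extended_alphabet_matrix(matrix)
            pio.write_score_matrix(list(ext), scores, out_dir / "custom_matrix.txt",
                                   metadata=matrix.metadata)

    # --- assign -------------------------------------------------------
    groups: list[orthology.OrthologGroup] = []
    family_by_group: dict[str, simulate.SimulatedFamily] = {}
    if "assign" in config.stages:
        if matrix is None:
            raise RuntimeError("assign requires build-matrix")
        reference_taxon = seq_taxa[0]
        profiles = []
        reference_proteome: dict[str, str] = {}
        queries: dict[str, dict[str, str]] = {t: {} for t in seq_taxa}
        for g, family in enumerate(families):
            gid = f"OG{g:04d}"
            family_by_group[gid] = family
            members = []
            for label, seq in sorted(family.sequences.items()):
                taxon, copy = paralogs.parse_leaf_label(label)
                if taxon == reference_taxon and not any(
                    m[0] == reference_taxon for m in members
                ):
                    members.append((taxon, f"{gid}_ref", seq))
                    reference_proteome[f"{gid}_ref"] = seq
                else:
                    queries.setdefault(taxon, {})[f"{gid}@{label}"] = seq
            if not members:
                continue  # reference taxon lost from this family
            cluster = submat.Cluster(id=gid, members=members)
            profiles.append(orthology.build_profile(cluster, matrix, reference_taxon))
        null = orthology.EmpiricalNull(n_shuffles=200, seed=config.seed)
        groups = orthology.assign_orthologs(
            queries, profiles, reference_proteome, matrix,
            evalue_cutoff=config.evalue, quartile_fraction=config.quartile,
            null=null,
        )
        manifest.record(
            "assign",
            n_profiles=len(profiles),
            n_queries=sum(len(v) for v in queries.values()),
            n_groups_with_hits=sum(1 for g in groups if g.members),
            n_assigned=sum(len(v) for g in groups for v in g.members.values()),
        )

    # --- prune --------------------------------------------------------
    pruned: list[paralogs.PrunedGroup] = []
    if "prune" in config.stages:
        n_out = 0
        for group in groups:
            family = family_by_group.get(group.group_id)
            if family is None or not group.members:
                continue
            sequences = {}
            for taxon, entries in group.members.items():
                for sid, seq in entries:
                    label = sid.split("@", 1)[1] if "@" in sid else f"{taxon}@{sid}"
                    sequences[label] = seq
            tree = family.gene_tree.extract_tree_with_taxa_labels(sequences.keys())
            result = paralogs.prune_group(
                tree, sequences, group_id=group.group_id,
                support_threshold=config.support_cutoff,
            )
            n_out += result.had_out_paralogs
            pruned.append(result)
        eligible = paralogs.occupancy_filter(
            pruned, total_taxa=len(seq_taxa), min_fraction=config.occupancy
        )
        manifest.record(
            "prune",
            groups_in=len(pruned),
            groups_with_out_paralogs=n_out,
            groups_eligible=len(eligible),
        )
        pruned = eligible

    # --- supermatrix --------------------------------------------------
    matrix_obj = None
    if "supermatrix" in config.stages:
        codon_alignments = []
        for group in pruned:
            family = family_by_group.get(group.group_id)
            prot_rows = dict(group.consensus)
            cds = {}
            for taxon, seq in prot_rows.items():
                source = None
                if family is not None:
                    for label, fam_seq in family.sequences.items():
                        if label.startswith(taxon + "@") and fam_seq == seq.replace("-", ""):
                            source = family.cds[label]
                            break
                if source is None:
                    # consensus differs from any single copy: re-derive a CDS
                    source = _cds_for(seq.replace("-", ""))
                cds[taxon] = source
            codon_alignments.append(
                sm.backtranslate(prot_rows, cds, group_id=group.group_id)
            )
        matrix_obj = sm.concatenate(codon_alignments, taxon_set=seq_taxa)
        before = matrix_obj.n_sites
        matrix_obj = sm.filter_codon_columns(matrix_obj, min_taxa=config.min_col_taxa)
        stats = sm.matrix_stats(matrix_obj)
        manifest.record(
            "supermatrix",
            n_groups=stats.n_groups,
            sites_before_filter=before,
            n_sites=stats.n_sites,
            percent_complete=stats.percent_complete,
            percent_ambiguous=stats.percent_ambiguous,
        )
        if out_dir:
            sm.export(matrix_obj, out_dir)

    # --- asr ----------------------------------------------------------
    if "asr" in config.stages:
        truth = simulate.simulate_binary_trait(
            species_tree, simulate.RateModel.er(config.trait_rate),
            root_state=0, seed=config.seed + 1,
        )
        observed = simulate.apply_missingness(
            {t: str(s) for t, s in truth.tip_states.items()},
            config.unknown_fraction, seed=config.seed + 2,
        )
        traits = mkasr.TraitTable(observed)
        ti = mkasr.TreeIndex(species_tree)
        fits = [
            mkasr.fit_mk(ti, traits, kind, root_prior=config.root_prior)
            for kind in ("ER", "ARD")
        ]
        chosen = mkasr.model_select(fits)
        recon = mkasr.marginal_asr(
            ti, traits, chosen, root_prior=config.root_prior,
            sig_threshold=config.sig_threshold,
        )
        manifest.record(
            "asr",
            n_tips=config.n_taxa,
            n_unknown=sum(1 for v in observed.values() if v == "unknown"),
            aicc_table={f.model.kind: round(f.AICc, 5) for f in fits},
            chosen_model=chosen.model.kind,
            chosen_rates={"q01": chosen.model.q01, "q10": chosen.model.q10},
            lnL=chosen.lnL,
            n_significant=sum(recon.significant.values()),
            n_internal_nodes=len(recon.nodes),
        )
        if out_dir:
            with open(out_dir / "asr_nodes.tsv", "w") as fh:
                fh.write("node\tp_indirect\tp_direct\tsignificant\tdirection\n")
                for row in mkasr.reconstruction_rows(recon):
                    fh.write("\t".join(str(x) for x in row) + "\n")
            pio.write_newick(mkasr.annotate_tree(species_tree, recon),
                             out_dir / "asr_annotated.nwk")

    if out_dir:
        manifest.to_json(out_dir / "manifest.json")
    return manifest


def _cds_for(protein: str) -> str:
    """Deterministic CDS for a protein (first codon of each residue)."""
    table = simulate._codon_table()
    return "".join(table.get(aa, ["NNN"])[0] if aa != "X" else "NNN" for aa in protein)
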