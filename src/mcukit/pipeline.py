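"""End-to-end orchestration: fixtures, the co-evolution run, quantification.

``generate_fixtures`` writes a complete synthetic dataset — species tree,
per-family gene trees (including an opisthokont-style duplication with
three chytrid-like species retaining both paralogs), proteomes with
planted domains, seed alignments, similarity-candidate lists, taxonomy,
ground truth, and a simulated aequorin plate — that exercises every stage.

``run_coevolution`` executes screen -> orthology -> profiling ->
conservation scan on such a dataset and emits the presence/absence matrix,
co-occurrence statistics, flagged clade-contrast columns, and a manifest;
``run_quantify`` runs the aequorin chain on a plate.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import aequorin, conservation, io, orthology, profiling, screen, simulate
from .alphabet import mutate, random_protein
from .screen import Alignment, ScreenConfig

ROLE_FILES = {
    "MCU-domain": "MCU-domain.afa",
    "Mito_carr": "Mito_carr.afa",
    "DDDD": "DDDD.afa",
    "NCLX-domain": "NCLX-domain.afa",
}

HOLOZOA = ["h1", "h2", "h3", "h4"]
CHYTRIDS = ["c1", "c2", "c3"]
FUNGI = ["f1", "f2", "f3", "f4"]
ALL_SPECIES = HOLOZOA + CHYTRIDS + FUNGI

_LINEAGES = {
    **{s: ("Eukaryota", "Opisthokonta", "Holozoa") for s in HOLOZOA},
    **{s: ("Eukaryota", "Opisthokonta", "Holomycota", "Chytridiomycota")
       for s in CHYTRIDS},
    **{s: ("Eukaryota", "Opisthokonta", "Holomycota", "Dikarya")
       for s in FUNGI},
}

# which species carry each family in the demo dataset (the truth)
DEMO_PRESENCE = {
    "MCU": HOLOZOA + CHYTRIDS,
    "MCUP": CHYTRIDS + FUNGI,
    "MICU": HOLOZOA + CHYTRIDS,
    "EMRE": HOLOZOA + CHYTRIDS,
    "NCLX": ALL_SPECIES,
    "ARALAR": ALL_SPECIES,
}

TEMPLATE_LENGTHS = {"MCU-domain": 48, "Mito_carr": 40, "DDDD": 24,
                    "NCLX-domain": 44}


def _subtree_newick(species: list[str], gene_prefix: str) -> str:
    """Species-tree-congruent caterpillar-free topology for a species subset."""
    def build(spp):
        if len(spp) == 1:
            sp = spp[0]
            return f"'{sp}|{gene_prefix}_{sp}'"
        mid = len(spp) // 2
        return f"({build(spp[:mid])},{build(spp[mid:])})"
    return build(species)


def demo_gene_trees() -> dict[str, str]:
    """Newick gene trees for the demo families.

    The MCU family tree is rooted on a duplication whose two children are
    the animal-like clade (holozoa + chytrids) and the MCUP clade
    (chytrids + fungi): the three chytrid-like species appear in both, the
    structure behind the opisthokont-duplication reading of the real trees.
    """
    mcu = (f"({_subtree_newick(HOLOZOA + CHYTRIDS, 'MCU')},"
           f"{_subtree_newick(CHYTRIDS + FUNGI, 'MCUP')});")
    trees = {"MCU": mcu}
    for fam in ("MICU", "EMRE", "NCLX", "ARALAR"):
        trees[fam] = _subtree_newick(DEMO_PRESENCE[fam], fam) + ";"
    return trees


def demo_templates(seed: int) -> dict[str, str]:
    rng = np.random.default_rng(seed + 17)
    return {role: random_protein(n, rng)
            for role, n in TEMPLATE_LENGTHS.items()}


def _seed_alignment(template: str, rng, n_seqs: int = 4,
                    divergence: float = 0.05) -> Alignment:
    rows = [(f"seed{i + 1}", mutate(template, divergence, rng))
            for i in range(n_seqs)]
    return Alignment.from_pairs(rows)


def second_iteration_fixture(seed: int = 0, n_distant: int = 3):
    """Sequence set in which divergent homologs surface only at iteration 2.

    Emulates the hardest screening case: a short, compositionally biased
    (low-complexity) domain family whose members are barely separable from
    background — the situation of the polyaspartate-carrying single-pass
    regulator.  The seed alignment knows the ancestral template; the
    proteome holds one moderately diverged homolog plus relatives that
    diverged further *through* it, sharing its substitutions.  The distant
    relatives are drawn by rejection against the two search states: each
    must score below the iteration-1 cutoff under the seed profile but at
    or above the iteration-2 cutoff under the profile rebuilt from the
    iteration-1 hit, so the second search pass is what discovers them.

    Returns (seed_alignment, sequences, close_ids, distant_ids, cfg,
    background).
    """
    from .alphabet import biased_background
    from .screen import build_profile, calibrate_threshold, _window_scores
    from .alphabet import encode

    bg = biased_background()
    rng = np.random.default_rng(seed + 1009)
    template = random_protein(24, rng, bg)
    aln = Alignment.from_pairs(
        [(f"seed{i + 1}", mutate(template, 0.03, rng, bg)) for i in range(4)])
    cfg = ScreenConfig(max_iterations=2, fpr=1e-3, n_null=10_000,
                       null_length=120, seed=seed)
    close_core = mutate(template, 0.2, rng, bg)
    close_id = "spA|close1"
    sequences = {close_id: (random_protein(25, rng, bg) + close_core
                            + random_protein(25, rng, bg))}
    # iteration-1 search state: seed profile + its empirical-null cutoff
    profile1 = build_profile(aln, cfg.pseudocount_weight, bg)
    thr1 = calibrate_threshold(profile1, fpr=cfg.fpr, n_null=cfg.n_null,
                               null_length=cfg.null_length, seed=cfg.seed)
    # iteration-2 state: profile rebuilt from the sole iteration-1 hit
    profile2 = build_profile(Alignment.from_pairs([("hit", close_core)]),
                             cfg.pseudocount_weight, bg)
    thr2 = calibrate_threshold(profile2, fpr=cfg.fpr, n_null=cfg.n_null,
                               null_length=cfg.null_length, seed=cfg.seed + 1)

    def max_score(profile, seq):
        return float(_window_scores(profile, encode(seq)[None, :]).max())

    if not max_score(profile1, sequences[close_id]) >= thr1:
        raise AssertionError("close homolog must be found in iteration 1")
    distant_ids = []
    attempts = 0
    while len(distant_ids) < n_distant and attempts < 2000:
        attempts += 1
        core = mutate(close_core, 0.35, rng, bg)
        seq = random_protein(25, rng, bg) + core + random_protein(25, rng, bg)
        if (max_score(profile1, seq) < thr1 - 1.0
                and max_score(profile2, seq) >= thr2 + 1.0):
            did = f"spB{len(distant_ids) + 1}|distant{len(distant_ids) + 1}"
            sequences[did] = seq
            distant_ids.append(did)
    if len(distant_ids) < n_distant:
        raise AssertionError("could not construct second-iteration homologs")
    for i in range(40):
        seq = random_protein(120, rng, bg)
        # decoys must stay decoys under both search states
        if max_score(profile1, seq) >= thr1 or max_score(profile2, seq) >= thr2:
            continue
        sequences[f"spZ|decoy{i + 1}"] = seq
    return aln, sequences, [close_id], distant_ids, cfg, bg


def _plate_fixture(seed: int):
    """Simulated aequorin plate: three strains, three wells each."""
    # peaks chosen so a substantial reporter pool survives to lysis (the
    # protocol's residual counts), keeping the calibration well-conditioned
    group_peaks = {"HsMCU+HsEMRE": 2e-5, "SpMCU+SpEMRE": 1.4e-5,
                   "empty-vector": 2e-6}
    constants = aequorin.CalibrationConstants()
    rows, wells_meta, truth = [], {}, {}
    well_no = 0
    for g, (group, peak) in enumerate(sorted(group_peaks.items())):
        true_ca = simulate.bell_transient(n=240, dt=0.5, peak_ca=peak)
        for r in range(3):
            well_no += 1
            well = f"W{well_no:02d}"
            trace, _ = simulate.simulate_luminescence(
                true_ca, constants, total_counts=1e5, dt=0.5,
                noise=True, seed=seed + 31 * g + r)
            for t, c in zip(trace.times, trace.counts):
                rows.append((well, float(t), float(c)))
            wells_meta[well] = {"lysis_counts": trace.lysis_counts,
                                "group": group}
            truth[well] = {"group": group, "true_peak": peak}
    plate_df = pd.DataFrame(rows, columns=["well", "time_s", "counts"])
    meta = {"wells": wells_meta, "stimulus_time": 10.0, "smoothing_p": 0.5,
            "constants": {"lambda": 1.0, "K_R": 7.23e6, "K_TR": 120.0,
                          "n": 2.99}}
    return plate_df, meta, truth


def generate_fixtures(out_dir, seed: int = 0, scale: str = "demo") -> Path:
    """Write a complete synthetic dataset under ``out_dir``.

    ``scale='tiny'`` shrinks decoy counts and the plate for smoke tests;
    byte-identical for identical (seed, scale).
    """
    if scale not in ("tiny", "demo"):
        raise ValueError("scale must be 'tiny' or 'demo'")
    out = Path(out_dir)
    for sub in ("gene_trees", "proteomes", "seeds", "truth"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    decoys = 4 if scale == "tiny" else 15
    cfg = simulate.SimulationConfig(n_species=len(ALL_SPECIES), seed=seed,
                                    domain_divergence=0.1,
                                    decoys_per_proteome=decoys)
    trees = demo_gene_trees()
    for fam, newick in trees.items():
        (out / "gene_trees" / f"{fam}.nwk").write_text(newick + "\n")
    templates = demo_templates(seed)
    # MCUP carries a diverged copy of the MCU domain: still detectable by
    # the MCU-domain profile, but with clade-specific residues for the
    # conservation scan to flag
    mcup_rng = np.random.default_rng(seed + 41)
    family_templates = {"MCU": templates["MCU-domain"],
                        "MCUP": mutate(templates["MCU-domain"], 0.25, mcup_rng),
                        "MICU": random_protein(
                            42, np.random.default_rng(seed + 23)),
                        "EMRE": templates["DDDD"],
                        "NCLX": templates["NCLX-domain"],
                        "ARALAR": templates["Mito_carr"]}
    family_trees = {}
    for fam, newick in trees.items():
        tree = orthology.read_gene_tree(newick)
        if fam == "MCU":
            labels = orthology.annotate_events(tree)
            a, b = orthology.split_paralog_clades(tree, labels,
                                                 tree.seed_node,
                                                 ("MCU", "MCUP"))
            family_trees["MCU"] = _prune_to(tree, a.genes)
            family_trees["MCUP"] = _prune_to(tree, b.genes)
        else:
            family_trees[fam] = tree
    proteomes, history = simulate.plant_domains(
        family_trees, family_templates, cfg, species_universe=ALL_SPECIES)
    for sp, seqs in proteomes.items():
        io.write_fasta(out / "proteomes" / f"{sp}.fasta", seqs)
    rng = np.random.default_rng(seed + 5)
    for role, fname in ROLE_FILES.items():
        io.write_alignment(out / "seeds" / fname,
                           _seed_alignment(templates[role], rng))
    candidates = []
    for fam, target in (("MICU", "MICU"), ("ARALAR", "MICU"),
                        ("NCLX", "NCLX")):
        tree = family_trees[fam]
        for _, seq_id in simulate.gene_leaves(tree):
            candidates.append((target, seq_id))
    pd.DataFrame(candidates, columns=["family", "seq_id"]).to_csv(
        out / "candidates.tsv", sep="\t", index=False)
    taxonomy = pd.DataFrame(
        [(sp, sp, ";".join(_LINEAGES[sp])) for sp in ALL_SPECIES],
        columns=["strain", "species", "lineage"])
    taxonomy.to_csv(out / "taxonomy.tsv", sep="\t", index=False)
    presence = pd.DataFrame(
        {fam: [int(sp in DEMO_PRESENCE[fam]) for sp in ALL_SPECIES]
         for fam in DEMO_PRESENCE}, index=pd.Index(ALL_SPECIES, name="species"))
    presence.to_csv(out / "truth" / "presence.tsv", sep="\t")
    domain_rows = [(sid, s, e, fam) for sid, ivs in sorted(history.domains.items())
                   for (s, e, fam) in ivs]
    pd.DataFrame(domain_rows, columns=["seq_id", "start", "end", "family"]
                 ).to_csv(out / "truth" / "domains.tsv", sep="\t", index=False)
    plate_df, meta, plate_truth = _plate_fixture(seed)
    plate_df.to_csv(out / "plate.csv", index=False)
    (out / "plate_meta.json").write_text(json.dumps(meta, indent=1))
    (out / "truth" / "plate.json").write_text(json.dumps(plate_truth, indent=1))
    config = default_coevolution_config(out, out / "results", seed)
    (out / "config.json").write_text(json.dumps(config, indent=1, default=str))
    return out


def _prune_to(tree, keep_genes):
    sub = tree.clone(depth=1)
    sub.retain_taxa_with_labels(sorted(keep_genes))
    sub.is_rooted = True
    for leaf in sub.leaf_node_iter():
        leaf.species = orthology.leaf_species(leaf)
    return sub


def default_coevolution_config(fixture_dir, out_dir, seed: int = 0) -> dict:
    fixture_dir = Path(fixture_dir)
    return {
        "proteome_dir": str(fixture_dir / "proteomes"),
        "seed_dir": str(fixture_dir / "seeds"),
        "gene_tree_dir": str(fixture_dir / "gene_trees"),
        "candidates": str(fixture_dir / "candidates.tsv"),
        "taxonomy": str(fixture_dir / "taxonomy.tsv"),
        "out_dir": str(out_dir),
        "fpr": 1e-3,
        "n_null": 10_000,
        "null_length": 200,
        "max_iterations": 2,
        "pseudocount_weight": 1.0,
        "pairs": [["MCU", "MICU"], ["MCU", "EMRE"], ["MCUP", "MICU"]],
        "n_perm": 999,
        "paralog_split": {
            "family": "MCU",
            "tags": {"MCU": HOLOZOA, "MCUP": FUNGI},
        },
        "conservation": {"family_a": "MCU", "family_b": "MCUP",
                         "theta_divergence": 0.5, "theta_conservation": 0.7,
                         "pseudocount": 0.5, "top_k": 10},
        "seed": seed,
    }


def _validate_paths(config: dict, keys) -> None:
    for key in keys:
        path = Path(config[key])
        if not path.exists():
            raise FileNotFoundError(f"config[{key!r}] does not exist: {path}")
        if path.is_dir() and not any(path.iterdir()):
            raise ValueError(f"config[{key!r}] is an empty directory: {path}")


def run_coevolution(config: dict) -> io.RunManifest:
    """screen -> orthology -> profiling -> conservation on one dataset."""
    _validate_paths(config, ("proteome_dir", "seed_dir", "gene_tree_dir",
                             "candidates", "taxonomy"))
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = io.config_hash(config)
    manifest = io.RunManifest(cfg_hash)
    (out / "config.json").write_text(json.dumps(config, indent=1, default=str))

    # --- screen ---------------------------------------------------------
    sequences: dict[str, str] = {}
    for fasta in sorted(Path(config["proteome_dir"]).glob("*.fasta")):
        sequences.update(io.read_fasta(fasta))
    scfg = ScreenConfig(max_iterations=int(config["max_iterations"]),
                        fpr=float(config["fpr"]),
                        n_null=int(config["n_null"]),
                        null_length=int(config.get("null_length", 200)),
                        pseudocount_weight=float(config["pseudocount_weight"]),
                        seed=int(config["seed"]))
    hits_by_profile: dict[str, list[screen.DomainHit]] = {}
    roles: dict[str, str] = {}
    all_hits = []
    for role, fname in ROLE_FILES.items():
        seed_aln = io.read_alignment(Path(config["seed_dir"]) / fname)
        hits, profiles = screen.iterative_search(
            seed_aln, sequences, scfg, profile_id=role, family_role=role)
        hits_by_profile[role] = hits
        roles[role] = role
        all_hits.extend(hits)
        io.write_profile(out / f"profile_{role}.json", profiles[-1])
    io.write_hits(out / "hits.tsv", all_hits, cfg_hash)
    cand_df = pd.read_csv(config["candidates"], sep="\t", comment="#")
    similarity = {fam: set(sub["seq_id"])
                  for fam, sub in cand_df.groupby("family")}
    assignments = screen.classify_family(hits_by_profile, roles, similarity)
    io.write_assignments(out / "assignments.tsv", assignments, cfg_hash)

    # --- orthology ------------------------------------------------------
    split = config["paralog_split"]
    split_family = split["family"]
    tree = io.read_tree(Path(config["gene_tree_dir"]) / f"{split_family}.nwk")
    labels = orthology.annotate_events(tree)
    if labels[tree.seed_node] != orthology.DUPLICATION:
        raise ValueError(f"{split_family} gene tree root is not a duplication; "
                         "cannot split paralog clades")
    clade_a, clade_b = orthology.split_paralog_clades(
        tree, labels, tree.seed_node, ("cladeA", "cladeB"))
    clades = _tag_clades((clade_a, clade_b), split["tags"])
    pairs_set = orthology.ortholog_pairs(tree, labels)
    pd.DataFrame(sorted(pairs_set), columns=["geneA", "geneB", "relation"]
                 ).to_csv(out / "ortholog_pairs.tsv", sep="\t", index=False)
    events = orthology.events_by_leafset(tree, labels)
    pd.DataFrame([(";".join(sorted(k)), v) for k, v in sorted(events.items())],
                 columns=["leafset", "event"]
                 ).to_csv(out / "events.tsv", sep="\t", index=False)
    (out / "clades.json").write_text(json.dumps(
        {c.subfamily: sorted(c.genes) for c in clades}, indent=1))

    # --- profiling ------------------------------------------------------
    taxonomy = profiling.TaxonomyMap.from_table(
        pd.read_csv(config["taxonomy"], sep="\t", comment="#"))
    species = sorted(taxonomy.lineages)
    detected: dict[str, set[str]] = {}
    for sid, a in assignments.items():
        if a.family in ("MCU", "MICU", "EMRE", "NCLX"):
            detected.setdefault(a.family, set()).add(sid)
    columns: dict[str, dict[str, int]] = {}
    mcu_seqs = detected.get(split_family, set())
    for clade in clades:
        columns[clade.subfamily] = {
            sp: int(any(g in mcu_seqs and g.split("|")[0] == sp
                        for g in clade.genes)) for sp in species}
    for fam in ("MICU", "EMRE", "NCLX"):
        ids = detected.get(fam, set())
        columns[fam] = {sp: int(any(i.split("|")[0] == sp for i in ids))
                        for sp in species}
    matrix = pd.DataFrame(columns, index=pd.Index(species, name="species"))
    matrix = profiling.collapse_to_species(
        matrix, _identity_taxonomy(taxonomy, species))
    io.write_table(out / "presence_matrix.tsv", matrix, cfg_hash,
                   index_label="species")
    cooc = {}
    for fam_a, fam_b in config["pairs"]:
        res = profiling.cooccurrence(matrix, fam_a, fam_b)
        p = profiling.coevolution_test(matrix, fam_a, fam_b,
                                       int(config["n_perm"]),
                                       int(config["seed"]))
        cooc[f"{fam_a}:{fam_b}"] = {
            "n_both": res.n_both, "n_only_a": res.n_only_a,
            "n_only_b": res.n_only_b, "n_neither": res.n_neither,
            "jaccard": res.jaccard, "p_value": p}
    (out / "cooccurrence.json").write_text(json.dumps(cooc, indent=1))
    report = profiling.profile_report(matrix, taxonomy)
    io.write_table(out / "profile_report.tsv", report.table, cfg_hash,
                   index_label="species")
    (out / "complete_losses.json").write_text(
        json.dumps(report.complete_losses, indent=1))

    # --- conservation scan ----------------------------------------------
    ccfg = config["conservation"]
    fam_hits = hits_by_profile["MCU-domain"]
    group_of = {}
    for clade in clades:
        label = "A" if clade.subfamily == ccfg["family_a"] else "B"
        for g in clade.genes:
            group_of[g] = label
    windows = [(h.seq_id, sequences[h.seq_id][h.start:h.end])
               for h in fam_hits if h.seq_id in group_of]
    if windows:
        aln = Alignment.from_pairs(windows)
        flagged = conservation.scan_specificity(
            aln, {sid: group_of[sid] for sid, _ in windows},
            thresholds=(float(ccfg["theta_divergence"]),
                        float(ccfg["theta_conservation"])),
            pseudocount=float(ccfg["pseudocount"]),
            top_k=int(ccfg["top_k"]))
        pd.DataFrame([(s.column, s.divergence, s.conservation_a,
                       s.conservation_b, s.flagged) for s in flagged],
                     columns=["column", "divergence", "consA", "consB",
                              "flagged"]
                     ).to_csv(out / "specificity.tsv", sep="\t", index=False)
        all_scores = conservation.score_columns(
            aln, {sid: group_of[sid] for sid, _ in windows},
            float(ccfg["pseudocount"]),
            (float(ccfg["theta_divergence"]), float(ccfg["theta_conservation"])))
        (out / "specificity_strip.txt").write_text(
            conservation.render_strip(aln, all_scores))

    for artifact in sorted(out.iterdir()):
        if artifact.is_file() and artifact.name != "manifest.json":
            manifest.record(artifact)
    manifest.write(out / "manifest.json")
    return manifest


def _identity_taxonomy(taxonomy: profiling.TaxonomyMap, species) -> profiling.TaxonomyMap:
    return profiling.TaxonomyMap({sp: sp for sp in species},
                                 {sp: taxonomy.lineages[sp] for sp in species})


def _tag_clades(clades, tags: dict[str, list[str]]):
    """Assign subfamily names by overlap with the tag species hints."""
    tagged = []
    taken = set()
    for clade in clades:
        best, best_overlap = None, -1
        for tag, hint in tags.items():
            overlap = len(clade.species & set(hint))
            if overlap > best_overlap:
                best, best_overlap = tag, overlap
        if best in taken:
            raise ValueError("paralog-split tag hints do not separate the clades")
        taken.add(best)
        tagged.append(orthology.OrthologClade(best, clade.genes, clade.species,
                                              clade.defining_node))
    return tuple(tagged)


def run_quantify(config: dict) -> io.RunManifest:
    """Aequorin chain on a plate CSV + metadata JSON."""
    _validate_paths(config, ("plate", "meta"))
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = io.config_hash(config)
    manifest = io.RunManifest(cfg_hash)
    plate, groups, meta = io.read_plate(config["plate"], config["meta"])
    constants = io.constants_from_meta(meta)
    smoothing = aequorin.SmoothingConfig(
        p=float(config.get("smoothing_p", meta.get("smoothing_p", 0.5))))
    stimulus = float(config.get("stimulus_time", meta.get("stimulus_time", 0.0)))
    per_well, per_group = aequorin.quantify_experiment(
        plate, groups, stimulus, constants, smoothing)
    wells_df = pd.DataFrame(
        [(w, groups[w], s.peak, s.peak_time, s.left_slope, s.secant_slope)
         for w, s in sorted(per_well.items())],
        columns=["well", "group", "peak_M", "peak_time_s",
                 "left_slope_M_per_s", "secant_slope_M_per_s"])
    io.write_table(out / "wells.tsv", wells_df, cfg_hash)
    groups_df = pd.DataFrame(
        [(g.group, g.n, g.peak_mean, g.peak_sem, g.slope_mean, g.slope_sem)
         for g in per_group],
        columns=["group", "n", "peak_mean_M", "peak_sem_M",
                 "slope_mean_M_per_s", "slope_sem_M_per_s"])
    io.write_table(out / "groups.tsv", groups_df, cfg_hash)
    traces = []
    for well, trace in sorted(plate.items()):
        ca = aequorin.calibrate_trace(trace, constants, smoothing)
        traces.append(pd.DataFrame({"well": well, "time_s": ca.times,
                                    "ca_M": ca.ca}))
    pd.concat(traces).to_csv(out / "calibrated_traces.csv", index=False)
    for artifact in sorted(out.iterdir()):
        if artifact.is_file() and artifact.name != "manifest.json":
            manifest.record(artifact)
    manifest.write(out / "manifest.json")
    return manifest
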