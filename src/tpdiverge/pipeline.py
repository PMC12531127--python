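"""End-to-end orchestration: simulate → rbbh → infer → features → stats → asr.

Mirrors the script chain a practitioner would run by hand, persisting
every intermediate as TSV under the output directory and recording a
manifest (config, seed, versions, per-stage record counts).  A re-run
with the same config is byte-identical; nothing time-dependent is
written.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .asr import asr_table, asr_bm
from .config import CladeConfig, RunConfig
from .cstats import anova_bonferroni, subsample_robustness, summarize_species
from .features import compute_features, extract_window
from .io import (
    calls_frame,
    features_frame,
    rbbh_frame,
    seeds_frame,
    write_fasta,
    write_tsv,
)
from .localization import SeedSet, transfer_labels
from .records import LocalizationCall
from .rooting import mad_root
from .similarity import reciprocal_best_hits
from .synthetic import CladeSpec, SyntheticDataset, generate_clade
from .trees import deroot, write_newick

logger = logging.getLogger(__name__)


def clade_spec_from_config(cfg: CladeConfig, seed: int,
                           window_length: int = 20) -> CladeSpec:
    return CladeSpec(
        clade_name=cfg.name,
        n_species=cfg.n_species,
        n_families_per_organelle={
            "mito": cfg.n_mito, "plastid": cfg.n_plastid, "dual": cfg.n_dual
        },
        separation_delta=cfg.separation_delta,
        mutation_rate=cfg.mutation_rate,
        bm_sigma2=cfg.bm_sigma2,
        bm_root_state=cfg.bm_root_state,
        seed=seed,
        window_length=window_length,
    )


def derive_seed(base: int, index: int) -> int:
    """Per-clade seed, stable in the clade's position and below 2^31."""
    return (base * 100_003 + 7919 * index + 1) % (2**31)


def write_dataset(dataset: SyntheticDataset, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for sp in dataset.species:
        write_fasta(dataset.proteins_of(sp), outdir / f"{sp}.faa")
    write_tsv(
        seeds_frame(dataset.seed_annotations, dataset.seed_species),
        outdir / "seeds.tsv",
    )
    write_newick(dataset.species_tree, outdir / "species_tree.nwk")
    truth = pd.DataFrame(
        {
            "protein_id": sorted(dataset.true_localization),
            "organelle": [dataset.true_localization[k]
                          for k in sorted(dataset.true_localization)],
        }
    )
    write_tsv(truth, outdir / "truth.tsv")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # stage 1: simulate
    datasets: dict[str, SyntheticDataset] = {}
    for i, clade_cfg in enumerate(config.clades):
        spec = clade_spec_from_config(
            clade_cfg, derive_seed(config.seed, i), config.window_length
        )
        ds = generate_clade(spec)
        datasets[clade_cfg.name] = ds
        write_dataset(ds, out / "data" / clade_cfg.name)
        counts[f"simulate/{clade_cfg.name}/proteins"] = len(ds.proteomes)
    logger.info("simulated %d clades", len(datasets))

    clade_of = {
        sp: name for name, ds in datasets.items() for sp in ds.species
    }

    # stage 2+3: rbbh against the seed species, then label transfer
    all_calls: list[LocalizationCall] = []
    all_features = []
    all_windows: dict[str, str] = {}
    proteome_sizes: dict[str, int] = {}
    for name, ds in datasets.items():
        seeds = SeedSet(ds.seed_annotations, ds.seed_species, clade=name)
        seed_proteins = ds.proteins_of(ds.seed_species)
        clade_pairs = []
        clade_calls: list[LocalizationCall] = [
            LocalizationCall(pid, ds.seed_species, label, (pid,))
            for pid, label in sorted(ds.seed_annotations.items())
        ]
        for sp in ds.species:
            proteome_sizes[sp] = len(ds.proteins_of(sp))
            if sp == ds.seed_species:
                continue
            pairs = reciprocal_best_hits(
                ds.proteins_of(sp), seed_proteins,
                evalue_cutoff=config.evalue_cutoff,
            )
            clade_pairs.extend(pairs)
            clade_calls.extend(
                transfer_labels(
                    ds.proteins_of(sp), seeds, pairs,
                    conflict=config.conflict_rule,
                )
            )
        write_tsv(rbbh_frame(clade_pairs), out / f"rbbh_{name}.tsv")
        write_tsv(calls_frame(clade_calls), out / f"calls_{name}.tsv")
        counts[f"rbbh/{name}/pairs"] = len(clade_pairs)
        counts[f"calls/{name}"] = len(clade_calls)

        # stage 4: windows and features for called proteins
        by_id = {r.protein_id: r for r in ds.proteomes}
        feats = []
        for call in clade_calls:
            window = extract_window(
                by_id[call.protein_id], W=config.window_length,
                strip_met=config.strip_met,
            )
            all_windows[call.protein_id] = window.residues
            feats.append(compute_features(window))
        frame = features_frame(feats, clade_calls, all_windows, clade_of)
        write_tsv(frame, out / f"features_{name}.tsv")
        counts[f"features/{name}"] = len(feats)
        all_calls.extend(clade_calls)
        all_features.extend(feats)

    # stage 5: species summaries
    summaries = summarize_species(all_features, all_calls, proteome_sizes, clade_of)
    write_tsv(summaries, out / "summaries.tsv")
    counts["summaries"] = len(summaries)

    # stage 6: clade comparisons
    comparison_frames = []
    for trait in ("charge", "phospho"):
        comp = anova_bonferroni(summaries, trait, alpha=config.alpha)
        pw = comp.pairwise.copy()
        pw.insert(0, "trait", trait)
        pw["anova_F"] = comp.anova_F
        pw["anova_p"] = comp.anova_p
        comparison_frames.append(pw)
    comparisons = pd.concat(comparison_frames, ignore_index=True)
    write_tsv(comparisons, out / "comparisons.tsv")
    counts["comparisons"] = len(comparisons)

    # stage 6b: optional subsampling robustness
    if config.subsample_reps > 0:
        feature_tables = [
            pd.read_csv(out / f"features_{name}.tsv", sep="\t")
            for name in datasets
        ]
        table = pd.concat(feature_tables, ignore_index=True)
        names = list(datasets)
        comps = []
        if len(names) >= 1:
            comps.append(((names[0], "plastid"), (names[0], "mito")))
        if len(names) >= 2:
            comps.append(((names[0], "plastid"), (names[1], "plastid")))
            comps.append(((names[0], "plastid"), (names[1], "mito")))
        sub = subsample_robustness(
            table, comps,
            n_range=config.subsample_n, N_range=config.subsample_N,
            reps=config.subsample_reps, seed=config.seed, alpha=config.alpha,
        )
        write_tsv(sub, out / "subsample.tsv")
        counts["subsample"] = len(sub)

    # stage 7: MAD rooting + BM ancestral states per clade, organelle, trait
    for name, ds in datasets.items():
        if len(ds.species) >= 3:
            rooted = mad_root(deroot(ds.species_tree)).tree
        else:
            rooted = ds.species_tree  # MAD needs >= 3 tips; keep as generated
        write_newick(rooted, out / f"tree_{name}_mad.nwk")
        clade_summary = summaries[summaries["clade"] == name]
        asr_frames = []
        for organelle in ("mito", "plastid", "dual"):
            sub = clade_summary[clade_summary["organelle"] == organelle]
            if len(sub) < len(ds.species):
                continue  # ASR needs a value at every tip
            for trait, col in (("charge", "mean_charge"),
                               ("phospho", "mean_phospho")):
                traits = dict(zip(sub["species"], sub[col]))
                params, estimates = asr_bm(rooted, traits)
                tab = asr_table(estimates)
                tab.insert(0, "trait", trait)
                tab.insert(0, "organelle", organelle)
                tab["sigma2"] = params.sigma2
                tab["root_state"] = params.root_state
                asr_frames.append(tab)
        if asr_frames:
            asr_all = pd.concat(asr_frames, ignore_index=True)
            write_tsv(asr_all, out / f"asr_{name}.tsv")
            counts[f"asr/{name}"] = len(asr_all)

    manifest = {
        "tool": "tpdiverge",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": config.config_hash(),
        "record_counts": counts,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
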