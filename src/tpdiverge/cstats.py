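"""Species- and clade-level statistics of targeting-peptide features.

The unit of analysis is the species × organelle mean: every protein's
window features are averaged within a species and destination, and those
means are what clade-level tests, subsampling checks, and the
divergence-vs-proteome-size correlation operate on.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .asr import welch_t
from .features import TPFeatures
from .records import LocalizationCall

TRAITS = ("charge", "phospho")
_TRAIT_COLUMN = {"charge": "mean_charge", "phospho": "mean_phospho"}


def protein_feature_table(
    features: list[TPFeatures],
    calls: list[LocalizationCall],
    clades: dict[str, str],
) -> pd.DataFrame:
    """Tidy per-protein table joining window features with their calls.

    Raises if any feature's protein lacks a localization call.
    """
    call_map = {c.protein_id: c for c in calls}
    rows = []
    for f in features:
        call = call_map.get(f.protein_id)
        if call is None:
            raise ValueError(f"no localization call for protein {f.protein_id!r}")
        rows.append(
            {
                "protein_id": f.protein_id,
                "species": call.species,
                "clade": clades.get(call.species, ""),
                "organelle": call.label,
                "net_charge": f.net_charge,
                "phospho_count": f.phospho_count,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "species", "clade", "organelle",
                 "net_charge", "phospho_count"],
    )


def summarize_species(
    features: list[TPFeatures],
    calls: list[LocalizationCall],
    proteome_sizes: dict[str, int],
    clades: dict[str, str],
) -> pd.DataFrame:
    """One row per (species, organelle): arithmetic-mean window features.

    ``proteome_sizes`` gives the total protein count of each species'
    FASTA (not just the organelle-annotated part).
    """
    table = protein_feature_table(features, calls, clades)
    if table.empty:
        return pd.DataFrame(
            columns=["species", "clade", "organelle", "mean_charge",
                     "mean_phospho", "n_proteins", "proteome_size"]
        )
    grouped = (
        table.groupby(["species", "clade", "organelle"], as_index=False)
        .agg(
            mean_charge=("net_charge", "mean"),
            mean_phospho=("phospho_count", "mean"),
            n_proteins=("protein_id", "size"),
        )
        .sort_values(["species", "organelle"], ignore_index=True)
    )
    grouped["proteome_size"] = grouped["species"].map(proteome_sizes)
    return grouped


@dataclass
class CladeComparison:
    """One-way ANOVA over (clade × organelle) groups plus Bonferroni pairs."""

    trait: str
    groups: list[tuple[str, str]]
    anova_F: float
    anova_p: float
    pairwise: pd.DataFrame
    n_comparisons: int
    alpha: float = 0.05
    degenerate: bool = False


def anova_bonferroni(
    summaries: pd.DataFrame, trait: str, alpha: float = 0.05
) -> CladeComparison:
    """Clade × organelle comparison of species-mean features.

    One-way ANOVA across all groups with >= 2 species, then all pairwise
    Welch t-tests with Bonferroni adjustment (p_adj = min(1, p·m), m the
    number of pairs).  Groups whose values are all identical make the
    ANOVA undefined; that case is flagged, not an error.
    """
    col = _TRAIT_COLUMN[trait]
    values = {
        key: g[col].to_numpy(dtype=float)
        for key, g in summaries.groupby(["clade", "organelle"])
        if len(g) >= 2
    }
    if len(values) < 2:
        raise ValueError("need at least two groups with >= 2 species each")
    groups = sorted(values)
    pooled = np.concatenate([values[g] for g in groups])
    degenerate = bool(np.all(pooled == pooled[0]))
    if degenerate:
        F, p_anova = float("nan"), float("nan")
    else:
        F, p_anova = stats.f_oneway(*(values[g] for g in groups))

    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    rows = []
    for g1, g2 in pairs:
        t, p = welch_t(values[g1], values[g2])
        p_adj = min(1.0, p * m)
        rows.append(
            {
                "group1": "/".join(g1),
                "group2": "/".join(g2),
                "t": t,
                "p_raw": p,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return CladeComparison(
        trait=trait,
        groups=groups,
        anova_F=float(F),
        anova_p=float(p_anova),
        pairwise=pd.DataFrame(rows),
        n_comparisons=m,
        alpha=alpha,
        degenerate=degenerate,
    )


def violin_table(summaries: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Distributional summary per (clade, organelle): median, IQR, range."""
    col = _TRAIT_COLUMN[trait]
    return (
        summaries.groupby(["clade", "organelle"], as_index=False)[col]
        .agg(
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
            low="min",
            high="max",
            n_species="size",
        )
    )


def _species_means(sub: pd.DataFrame) -> pd.DataFrame:
    return sub.groupby(["species", "clade", "organelle"], as_index=False).agg(
        mean_charge=("net_charge", "mean"),
        mean_phospho=("phospho_count", "mean"),
    )


def subsample_robustness(
    protein_table: pd.DataFrame,
    comparisons: list[tuple[tuple[str, str], tuple[str, str]]],
    n_range: tuple[int, int] = (100, 300),
    N_range: tuple[int, int] = (6, 9),
    reps: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Robustness of the named comparisons to shrinking the dataset.

    Per replicate, a protein count n is drawn uniformly from ``n_range``
    and a species count N from ``N_range`` (inclusive); N species per
    clade and n proteins per (species, organelle) are then sampled
    uniformly without replacement, species means recomputed, and each
    named (clade, organelle)-pair comparison re-tested (Welch, both
    traits, Bonferroni across the comparison family by default).
    Deterministic under the seed.  Raises when a draw exceeds what the
    data can supply.
    """
    columns = ["rep", "n", "N", "group1", "group2", "trait", "t", "p_raw",
               "p_adj", "significant"]
    if reps == 0:
        return pd.DataFrame(columns=columns)
    rng = np.random.default_rng(seed)
    clades_needed = sorted({g[0] for pair in comparisons for g in pair})
    species_by_clade = {
        c: sorted(protein_table.loc[protein_table["clade"] == c, "species"].unique())
        for c in clades_needed
    }
    m = len(comparisons) * len(TRAITS)
    rows = []
    for rep in range(reps):
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        N = int(rng.integers(N_range[0], N_range[1] + 1))
        kept = []
        for clade in clades_needed:
            pool = species_by_clade[clade]
            if N > len(pool):
                raise ValueError(
                    f"requested N={N} species but clade {clade!r} has {len(pool)}"
                )
            chosen = rng.choice(len(pool), size=N, replace=False)
            for idx in sorted(chosen):
                sp = pool[idx]
                sub = protein_table[protein_table["species"] == sp]
                for organelle, g in sub.groupby("organelle"):
                    if n > len(g):
                        raise ValueError(
                            f"requested n={n} proteins but {sp}/{organelle} "
                            f"has {len(g)}"
                        )
                    take = rng.choice(len(g), size=n, replace=False)
                    kept.append(g.iloc[sorted(take)])
        means = _species_means(pd.concat(kept, ignore_index=True))
        for (c1, o1), (c2, o2) in comparisons:
            v1 = means[(means["clade"] == c1) & (means["organelle"] == o1)]
            v2 = means[(means["clade"] == c2) & (means["organelle"] == o2)]
            for trait in TRAITS:
                col = _TRAIT_COLUMN[trait]
                t, p = welch_t(v1[col].to_numpy(), v2[col].to_numpy())
                p_adj = min(1.0, p * m) if bonferroni else p
                rows.append(
                    {
                        "rep": rep,
                        "n": n,
                        "N": N,
                        "group1": f"{c1}/{o1}",
                        "group2": f"{c2}/{o2}",
                        "trait": trait,
                        "t": t,
                        "p_raw": p,
                        "p_adj": p_adj,
                        "significant": p_adj < alpha,
                    }
                )
    return pd.DataFrame(rows, columns=columns)


def divergence_size_correlation(summaries: pd.DataFrame) -> pd.DataFrame:
    """Correlation of per-species mTP/pTP divergence with proteome size.

    Divergence per species: ``pTP mean_phospho − mTP mean_phospho`` for
    the phospho trait and ``mTP mean_charge − pTP mean_charge`` for the
    charge trait (each positive when the destinations are well
    separated); each is correlated (Pearson and Spearman) against total
    proteome size over species carrying both destinations.
    """
    wide = summaries.pivot_table(
        index=["species", "proteome_size"],
        columns="organelle",
        values=["mean_charge", "mean_phospho"],
    )
    needed = [("mean_charge", "mito"), ("mean_charge", "plastid"),
              ("mean_phospho", "mito"), ("mean_phospho", "plastid")]
    for colpair in needed:
        if colpair not in wide.columns:
            raise ValueError("need species with both mito and plastid summaries")
    wide = wide.dropna(subset=needed)
    if len(wide) < 3:
        raise ValueError("need at least 3 species with both mTP and pTP summaries")
    size = wide.index.get_level_values("proteome_size").to_numpy(dtype=float)
    divergences = {
        "charge": (wide[("mean_charge", "mito")]
                   - wide[("mean_charge", "plastid")]).to_numpy(),
        "phospho": (wide[("mean_phospho", "plastid")]
                    - wide[("mean_phospho", "mito")]).to_numpy(),
    }
    rows = []
    for trait, div in divergences.items():
        constant = bool(np.all(div == div[0])) or bool(np.all(size == size[0]))
        if constant:
            pear = (float("nan"), float("nan"))
            spear = (0.0, float("nan"))
        else:
            pear = stats.pearsonr(div, size)
            spear = stats.spearmanr(div, size)
        rows.append(
            {
                "trait": trait,
                "n_species": len(div),
                "pearson_r": float(pear[0]),
                "pearson_p": float(pear[1]),
                "spearman_rho": float(spear[0]),
                "spearman_p": float(spear[1]),
                "constant": constant,
            }
        )
    return pd.DataFrame(rows)
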