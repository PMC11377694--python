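"""Tabular input/output, run configuration and the end-to-end pipeline.

All artifacts are plain TSV/CSV with headers; the delimiter is inferred
from the file extension. ``run_pipeline`` chains filtering, transforms,
diversity, repeatability, cross-timepoint correlation, PLS stability and
(optionally) GBLUP into one output directory of TSV tables, with every
stochastic stage seeded from one global seed via a stage-name hash so any
stage is reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlation, diversity, genomic, pls, preprocess, repeatability
from .simulate import stage_seed

__all__ = [
    "StudyTables",
    "RunConfig",
    "read_study_tables",
    "read_genotype_matrix",
    "build_tensor",
    "run_pipeline",
]

logger = logging.getLogger("rumenstab")

TIMEPOINTS = [f"T{i}" for i in range(1, 7)]
FLOAT_FMT = "%.12g"


@dataclass
class StudyTables:
    """Aligned counts, per-sample metadata and per-animal phenotypes."""

    counts: pd.DataFrame
    metadata: pd.DataFrame
    phenotypes: pd.DataFrame

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts contain negative entries")
        missing = [s for s in self.counts.index if s not in self.metadata.index]
        if missing:
            raise ValueError(f"sample {missing[0]!r} missing from metadata")
        self.metadata = self.metadata.loc[self.counts.index]
        pairs = self.metadata[["animal_id", "timepoint"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            dup = pairs[pairs.duplicated()].iloc[0]
            raise ValueError(f"duplicate (animal, timepoint) pair {dup}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicated feature id {dup!r}")


@dataclass
class RunConfig:
    """Thresholds and seeds governing a pipeline run."""

    seed: int = 0
    n_permutations: int = 999
    alpha: float = 0.05
    vip_threshold: float = 0.8
    min_stable_timepoints: int = 4
    pseudocount: float = 0.5
    min_prevalence_fraction: float = 1.0
    min_mean_relabund: float = 1e-5
    n_components: int = 2
    transform: str = "ALR"  # or "CLR"
    include_additive_test: bool = False

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.vip_threshold <= 0:
            raise ValueError("vip_threshold must be positive")

    def validate_for(self, n_timepoints: int) -> None:
        if self.min_stable_timepoints > n_timepoints:
            raise ValueError(
                f"min_stable_timepoints={self.min_stable_timepoints} exceeds the "
                f"{n_timepoints} available timepoints"
            )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, comment="#")


def _check_unique_header(path) -> None:
    # pandas silently mangles duplicate column names; catch them at the source
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    names = [h for h in header[1:] if h]
    dupes = {h for h in names if names.count(h) > 1}
    if dupes:
        raise ValueError(f"duplicated feature id {sorted(dupes)[0]!r} in {path.name}")


def read_study_tables(counts_path, metadata_path, phenotypes_path) -> StudyTables:
    """Read and align the three study tables; see :class:`StudyTables`."""
    _check_unique_header(counts_path)
    counts = _read_table(counts_path)
    meta = _read_table(metadata_path)
    pheno = _read_table(phenotypes_path)
    return StudyTables(counts=counts, metadata=meta, phenotypes=pheno)


def read_genotype_matrix(path) -> tuple[pd.DataFrame, list[str]]:
    """Read a 0/1/2 dosage matrix; impute missing to per-marker mean dosage.

    Returns (matrix, monomorphic-marker ids); monomorphic markers are flagged
    so the caller can exclude them from the relationship matrix.
    """
    geno = _read_table(path)
    x = geno.to_numpy(dtype=float)
    valid = np.isnan(x) | np.isin(x, (0.0, 1.0, 2.0))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise ValueError(
            f"genotype entry {x[i, j]!r} at ({geno.index[i]}, {geno.columns[j]}) "
            "is outside {0, 1, 2, missing}"
        )
    col_mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), col_mean, x)
    geno = pd.DataFrame(x, index=geno.index, columns=geno.columns)
    p = x.mean(axis=0) / 2.0
    mono = [str(c) for c, pj in zip(geno.columns, p) if pj <= 0 or pj >= 1]
    return geno, mono


def build_tensor(matrix: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Re-index a sample x feature matrix by (animal_id, timepoint)."""
    meta = metadata.loc[matrix.index]
    out = matrix.copy()
    out.index = pd.MultiIndex.from_arrays(
        [meta["animal_id"], meta["timepoint"]], names=["animal_id", "timepoint"]
    )
    return out


def _write(df: pd.DataFrame, path: Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FMT)


def run_pipeline(
    config: RunConfig,
    tables: StudyTables,
    genotypes: pd.DataFrame | None = None,
    outdir="results",
    heritable_ids=None,
) -> Path:
    """Run every analysis stage and write one TSV per result into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tps = sorted(tables.metadata["timepoint"].unique())
    config.validate_for(len(tps))

    log_lines = [f"seed\t{config.seed}"]
    log_lines += [f"{k}\t{v}" for k, v in sorted(asdict(config).items()) if k != "seed"]

    def stage(name):
        logger.info("stage: %s", name)
        return stage_seed(config.seed, name)

    # --- filtering and transforms (modelling uses filtered, transformed data)
    stage("filter")
    filtered, report = preprocess.filter_features(
        tables.counts,
        min_prevalence_fraction=config.min_prevalence_fraction,
        min_mean_relabund=config.min_mean_relabund,
    )
    _write(
        pd.DataFrame(
            {
                "n_input_features": [report.n_input_features],
                "n_removed_prevalence": [report.n_removed_prevalence],
                "n_removed_abundance": [report.n_removed_abundance],
                "n_retained": [report.n_retained],
            }
        ),
        outdir / "filter_report.tsv",
    )

    stage("transform")
    if config.transform.upper() == "ALR":
        diag = preprocess.select_alr_denominator(filtered, pseudocount=config.pseudocount)
        transformed = preprocess.alr_transform(
            filtered, diag.selected, pseudocount=config.pseudocount
        )
        _write(diag.table, outdir / "denominator_diagnostics.tsv",
               f"selected={diag.selected} top_fraction={diag.top_fraction}")
    else:
        transformed = preprocess.clr_transform(filtered, pseudocount=config.pseudocount)
    _write(
        transformed.matrix,
        outdir / "transformed.tsv",
        f"transform={transformed.transform} denominator={transformed.denominator_id} "
        f"pseudocount={transformed.pseudocount}",
    )

    # --- diversity on unfiltered absolute counts
    alpha_tab = diversity.alpha_diversity_table(tables.counts)
    _write(alpha_tab, outdir / "alpha_diversity.tsv")
    alpha_test = diversity.alpha_timepoint_test(
        alpha_tab["adjusted_shannon"].to_numpy(), tables.metadata, alpha=config.alpha
    )
    _write(
        pd.DataFrame(
            {"wald_chi2": [alpha_test.wald_chi2], "df": [alpha_test.df], "p": [alpha_test.p]}
        ),
        outdir / "alpha_timepoint_test.tsv",
    )
    if alpha_test.pairwise is not None:
        _write(alpha_test.pairwise, outdir / "alpha_pairwise.tsv")

    bc = diversity.bray_curtis_matrix(tables.counts)
    _write(bc, outdir / "bray_curtis.tsv")
    perm = diversity.permanova(
        bc, tables.metadata["timepoint"].to_numpy(),
        n_permutations=config.n_permutations, seed=stage("permanova"),
    )
    _write(
        pd.DataFrame(
            {
                "pseudo_f": [perm.pseudo_f],
                "r2": [perm.r2],
                "p": [perm.p],
                "n_permutations": [perm.n_permutations],
            }
        ),
        outdir / "permanova.tsv",
    )
    if perm.p < config.alpha:
        pw = diversity.pairwise_permanova(
            bc, tables.metadata["timepoint"].to_numpy(),
            n_permutations=config.n_permutations, seed=stage("pairwise_permanova"),
        )
        _write(pw, outdir / "pairwise_permanova.tsv")
    f_disp, p_disp = diversity.permdisp(
        bc, tables.metadata["timepoint"].to_numpy(),
        n_permutations=config.n_permutations, seed=stage("permdisp"),
    )
    _write(pd.DataFrame({"f": [f_disp], "p": [p_disp]}), outdir / "permdisp.tsv")
    ordination = diversity.nmds(bc, k=2, seed=stage("nmds"))
    _write(
        ordination.configuration, outdir / "nmds.tsv", f"stress={ordination.stress:.6f}"
    )

    # --- per-feature mixed models on transformed abundances
    stage("repeatability")
    tmat = transformed.matrix
    tp_tests = repeatability.test_timepoint_effect(tmat, tables.metadata, alpha=config.alpha)
    _write(
        pd.DataFrame([vars(t) for t in tp_tests]).set_index("feature_id"),
        outdir / "timepoint_effect.tsv",
    )
    if config.include_additive_test:
        add_tests = repeatability.test_additive_effect(tmat, tables.metadata, alpha=config.alpha)
        _write(
            pd.DataFrame([vars(t) for t in add_tests]).set_index("feature_id"),
            outdir / "additive_effect.tsv",
        )

    rpt_both = repeatability.repeatability_table(tmat, tables.metadata, "both")
    rpt_con = repeatability.repeatability_table(tmat, tables.metadata, "CON")
    rpt_for = repeatability.repeatability_table(tmat, tables.metadata, "FOR")
    _write(pd.concat([rpt_both, rpt_con, rpt_for]).set_index("feature_id"),
           outdir / "repeatability.tsv")
    core = repeatability.core_microbiome(rpt_both, rpt_con, rpt_for, alpha=config.alpha)
    diet_p, _ = repeatability.compare_rpt_between_diets(
        rpt_con[rpt_con["feature_id"].isin(core["intersection"])],
        rpt_for[rpt_for["feature_id"].isin(core["intersection"])],
    ) if len(core["intersection"]) >= 5 else (np.nan, None)
    _write(
        pd.DataFrame(
            {
                "set": list(core.keys()),
                "n": [len(v) for v in core.values()],
                "members": [";".join(sorted(v)) for v in core.values()],
            }
        ),
        outdir / "core_microbiome.tsv",
        f"diet_rpt_comparison_p={diet_p}",
    )

    # --- cross-timepoint correlations
    tensor = build_tensor(tmat, tables.metadata)
    for label, subset in (("all", None), ("core", sorted(core["both"]) or None)):
        if label == "core" and not core["both"]:
            continue
        tc = correlation.timepoint_correlations(tensor, feature_subset=subset, subset_label=label)
        _write(tc.matrix, outdir / f"timepoint_correlations_{label}.tsv",
               f"subset={label} n_features={tc.n_features}")

    # --- PLS stability of trait associations
    stage("pls")
    traits = pls.residualize_traits(tables.phenotypes)
    animals = sorted(tensor.index.get_level_values("animal_id").unique())
    traits = traits.loc[animals]
    ev_table, models = pls.explained_variance_by_timepoint(
        tensor, traits, n_components=config.n_components
    )
    _write(ev_table.set_index(["trait", "timepoint"]), outdir / "explained_variance.tsv")
    stability_rows = []
    for trait in traits.columns:
        per_tp = {tp: m for (tr, tp), m in models.items() if tr == trait}
        sel = pls.stability_selection(
            per_tp, vip_threshold=config.vip_threshold,
            min_timepoints=config.min_stable_timepoints, trait=trait,
        )
        stability_rows.append(sel.table)
    _write(
        pd.concat(stability_rows).set_index(["trait", "feature_id"]),
        outdir / "pls_stability.tsv",
    )

    # --- GBLUP and EBV association (optional)
    if genotypes is not None:
        stage("gblup")
        p_freq = genotypes.to_numpy(dtype=float).mean(axis=0) / 2.0
        poly = (p_freq > 0) & (p_freq < 1)
        grel = genomic.vanraden_g(genotypes.loc[:, genotypes.columns[poly]])
        _write(grel.G, outdir / "G.tsv")
        meta_animal = tables.phenotypes.loc[grel.G.index]
        Xg = repeatability.design_matrix(meta_animal, ["diet", "breed"])
        ebv_rows = []
        for trait in [c for c in traits.columns]:
            fitg = genomic.fit_gblup(
                tables.phenotypes.loc[grel.G.index, trait].to_numpy(), Xg, grel
            )
            ebv_rows.append(
                pd.DataFrame(
                    {"animal_id": grel.G.index, "trait": trait,
                     "ebv": fitg.ebv.values, "h2": fitg.h2}
                )
            )
        ebv_table = pd.concat(ebv_rows)
        _write(ebv_table.set_index(["animal_id", "trait"]), outdir / "ebv.tsv")
        herit = list(map(str, heritable_ids)) if heritable_ids is not None else list(
            map(str, tensor.columns)
        )
        ebv_wide = ebv_table.pivot(index="animal_id", columns="trait", values="ebv")
        ebv_wide = ebv_wide.loc[animals]
        herit = [h for h in herit if h in set(map(str, tensor.columns))]
        if herit and ebv_wide.nunique().min() > 1:
            ev_ebv, stable_ebv = genomic.ebv_association(
                tensor, herit, ebv_wide,
                vip_threshold=config.vip_threshold,
                min_timepoints=config.min_stable_timepoints,
                n_components=config.n_components,
            )
            _write(ev_ebv.set_index(["trait", "timepoint"]), outdir / "ebv_explained_variance.tsv")
            _write(
                pd.concat([s.table for s in stable_ebv.values()]).set_index(
                    ["trait", "feature_id"]
                ),
                outdir / "ebv_stability.tsv",
            )

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return outdir
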