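"""End-to-end orchestration: simulate/load → filter → enrich → growth → stats.

:func:`run_pipeline` executes the full analysis under a :class:`RunConfig`,
writes every module's output table plus a ``manifest.json`` (config echo,
version, seeds, input checksums, per-stage record counts), and returns the
result bundle in memory.  Re-running with identical config and inputs
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import PipelineError
from .growth import (
    absolute_abundances,
    assimilation_table,
    flag_putative_predators,
    growing_sets,
    phylum_change,
    sample_summary,
    top_assimilators,
    treatment_overlap,
)
from .io import load_inputs, write_experiment, write_tsv
from .qsip import (
    DEFAULT_CONSTANTS,
    correct_wad_offset,
    enrich_all,
    filter_fractions,
    prevalence_filter,
)
from .simulate import ExperimentDesign, simulate_experiment
from .stats import (
    anova_two_way,
    bh_adjust,
    clr_transform,
    normality_homoscedasticity_gate,
    pca,
    permanova_two_way,
    rank_sum_test,
    welch_t_test,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a run needs; echoed verbatim into the manifest."""

    # inputs: either the four file paths, or a simulation design
    features: str | None = None
    fractions: str | None = None
    samples: str | None = None
    taxonomy: str | None = None
    simulate: bool = False
    design: ExperimentDesign = field(default_factory=ExperimentDesign)

    # filters and thresholds
    density_min: float = 1.614
    density_max: float = 1.753
    min_read_pairs: int = 2000
    min_fractions: int = 4
    min_replicates: int = 2
    ape_active_threshold: float = 0.0
    ape_growing_threshold: float = 5.0
    flagged_tubes: tuple = ()

    # growth summaries
    top_n: int = 5
    min_samples_top: int = 2

    # stats
    pseudocount: float = 1.0
    n_perm: int = 9999
    stats_seed: int = 7

    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design_raw = raw.pop("design", None)
        cfg = cls(**raw)
        if design_raw:
            cfg.design = ExperimentDesign(**design_raw)
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=str))


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's output."""

    enrichment: pd.DataFrame
    summary: pd.DataFrame
    assimilation: pd.DataFrame
    top: pd.DataFrame
    venn_regions: dict
    predators: pd.DataFrame
    ordination: pd.DataFrame
    variance_explained: list
    permanova: list
    manifest: dict


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run all stages and write the result bundle under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_jsonable(),
        "stages": {},
    }

    stage = "load"
    try:
        if config.simulate:
            sim = simulate_experiment(config.design)
            paths = write_experiment(sim, out / "inputs")
            features, fractions, samples, taxonomy = (
                sim.features, sim.fractions, sim.samples, sim.taxonomy,
            )
            manifest["inputs"] = {k: _checksum(v) for k, v in paths.items()}
            counts = {"n_taxa": int(features.shape[0]), "n_tubes": int(samples.shape[0])}
        else:
            features, fractions, samples, taxonomy, counts = load_inputs(
                config.features, config.fractions, config.samples, config.taxonomy
            )
            manifest["inputs"] = {
                k: _checksum(getattr(config, k))
                for k in ("features", "fractions", "samples", "taxonomy")
            }
        manifest["stages"][stage] = counts

        stage = "filter"
        kept = filter_fractions(
            fractions, config.density_min, config.density_max, config.min_read_pairs
        )
        if config.flagged_tubes:
            kept = correct_wad_offset(kept, samples, config.flagged_tubes, features)
        retained, coverage = prevalence_filter(
            features, kept, samples, config.min_fractions, config.min_replicates
        )
        manifest["stages"][stage] = {
            "fractions_retained": int(kept.shape[0]),
            "taxa_retained_per_treatment": {t: len(s) for t, s in retained.items()},
            "read_pair_coverage": {t: float(c) for t, c in coverage.items()},
        }

        stage = "enrich"
        enrichment = enrich_all(
            features, kept, samples, DEFAULT_CONSTANTS,
            config.ape_growing_threshold, config.ape_active_threshold, retained,
        )
        write_tsv(enrichment, out / "taxon_enrichment.tsv", index_label="row")
        manifest["stages"][stage] = {
            "rows": int(enrichment.shape[0]),
            "active_rows": int(enrichment["active"].sum()),
            "growing_rows": int(enrichment["growing"].sum()),
        }

        stage = "growth"
        abund = absolute_abundances(features, kept, samples, labeled_only=True)
        summary = sample_summary(enrichment, abund, samples)
        write_tsv(summary, out / "sample_summary.tsv", index_label="sample_id")
        records = assimilation_table(enrichment, abund, samples)
        write_tsv(records, out / "assimilation.tsv", index_label="row")
        top = top_assimilators(records, taxonomy, config.top_n, config.min_samples_top)
        write_tsv(top, out / "top_assimilators.tsv", index_label="row")
        gsets = growing_sets(enrichment, config.min_replicates)
        regions = treatment_overlap(gsets)
        regions_json = {"|".join(sorted(k)): v for k, v in regions.items()}
        with open(out / "venn_regions.json", "w") as fh:
            json.dump(regions_json, fh, indent=1, sort_keys=True)
        predators = taxonomy.loc[
            [t for t in taxonomy.index if flag_putative_predators(taxonomy.loc[t])]
        ]
        grown_anywhere = set().union(*gsets.values()) if gsets else set()
        predators = predators.assign(
            growing_in_any_treatment=[t in grown_anywhere for t in predators.index]
        )
        write_tsv(predators, out / "predators.tsv", index_label="taxon_id")

        # growing richness per phylum per sample, then drought-response changes
        growing_rows = enrichment[enrichment["growing"]]
        phyla = taxonomy.loc[growing_rows["taxon_id"], "phylum"].to_numpy()
        counts = (
            pd.DataFrame({"phylum": phyla, "sample": growing_rows["tube_id"].to_numpy()})
            .groupby(["phylum", "sample"]).size().unstack(fill_value=0)
            .reindex(columns=summary.index, fill_value=0)
        )
        sample_treatments = summary["treatment"]
        changes = []
        for ref, trt in (("ambient", "drought"), ("drought", "future_drought")):
            if {ref, trt} <= set(sample_treatments.unique()):
                ch = phylum_change(counts, sample_treatments, ref, trt)
                ch.insert(0, "comparison", f"{ref}->{trt}")
                changes.append(ch)
        if changes:
            write_tsv(pd.concat(changes), out / "phylum_change.tsv",
                      index_label="phylum")
        manifest["stages"][stage] = {
            "samples": int(summary.shape[0]),
            "assimilation_rows": int(records.shape[0]),
            "growing_sets": {t: len(s) for t, s in gsets.items()},
            "predator_taxa": int(predators.shape[0]),
        }

        stage = "stats"
        clr = clr_transform(abund.T, config.pseudocount)
        scores, _, var_exp = pca(clr)
        ordination = scores.copy()
        ordination.insert(0, "treatment", samples.loc[ordination.index, "treatment"].to_numpy())
        write_tsv(ordination, out / "ordination.tsv", index_label="sample_id")
        from scipy.spatial.distance import pdist, squareform

        dist = squareform(pdist(clr.to_numpy()))
        drought = samples.loc[clr.index, "drought"]
        climate = samples.loc[clr.index, "climate"]
        perma = permanova_two_way(
            dist, drought, climate, n_perm=config.n_perm, seed=config.stats_seed,
            names=("Drought", "Climate", "Drought:Climate"),
        )
        raw_p = [r.p for r in perma if r.term != "Residual"]
        adj = bh_adjust(raw_p)
        i = 0
        for r in perma:
            if r.term != "Residual":
                r.p_adj = float(adj[i])
                i += 1
        with open(out / "permanova.json", "w") as fh:
            json.dump([r.as_dict() for r in perma], fh, indent=1)

        # per-phylum two-way ANOVA (drought x climate) on growing richness,
        # gated on normality/homoscedasticity, BH-adjusted across phyla
        anova_rows = []
        sdrought = samples.loc[summary.index, "drought"]
        sclimate = samples.loc[summary.index, "climate"]
        rank_pairs = [("ambient", "drought"), ("drought", "future_drought")]
        if sdrought.nunique() > 1 and sclimate.nunique() > 1:
            for phylum, row in counts.iterrows():
                gate = normality_homoscedasticity_gate(
                    row.to_numpy(), sample_treatments.to_numpy()
                )
                if gate.decision == "anova":
                    res = anova_two_way(row.to_numpy(), sdrought, sclimate,
                                        names=("Drought", "Climate", "Drought:Climate"))
                    for r in res:
                        anova_rows.append({
                            "phylum": phylum, "method": "anova", "term": r.term,
                            "statistic": r.statistic, "df": r.df[0], "p": r.p,
                        })
                else:
                    # gate failed: pairwise rank-sum fallback per treatment pair
                    for a, b in rank_pairs:
                        xa = row[sample_treatments == a].to_numpy()
                        xb = row[sample_treatments == b].to_numpy()
                        if len(xa) < 2 or len(xb) < 2:
                            continue
                        r = rank_sum_test(xa, xb, label=f"{a} vs {b}")
                        anova_rows.append({
                            "phylum": phylum, "method": "rank-sum", "term": r.term,
                            "statistic": r.statistic, "df": r.df, "p": r.p,
                        })
        anova_df = pd.DataFrame(anova_rows)
        if not anova_df.empty:
            anova_df["p_adj"] = np.nan
            for term, idx in anova_df.groupby("term").groups.items():
                anova_df.loc[idx, "p_adj"] = bh_adjust(anova_df.loc[idx, "p"])
        write_tsv(anova_df, out / "anova.tsv", index_label="row")

        # pairwise Welch t-tests on per-sample mean growing RGR
        ttest_rows = []
        pairs = [("ambient", "drought"), ("future", "future_drought"),
                 ("drought", "future_drought"), ("ambient", "future")]
        by_treatment = summary.groupby("treatment")["mean_rgr_growing"]
        groups = {t: g.dropna().to_numpy() for t, g in by_treatment}
        for a, b in pairs:
            if a in groups and b in groups and len(groups[a]) > 1 and len(groups[b]) > 1:
                r = welch_t_test(groups[a], groups[b], label=f"{a} vs {b}")
                ttest_rows.append({"comparison": r.term, "t": r.statistic,
                                   "df": r.df, "p": r.p})
        ttest_df = pd.DataFrame(ttest_rows)
        if not ttest_df.empty:
            ttest_df["p_adj"] = bh_adjust(ttest_df["p"])
        write_tsv(ttest_df, out / "ttests.tsv", index_label="row")
        manifest["stages"][stage] = {
            "variance_explained_pc1_pc2": [float(v) for v in var_exp[:2]],
            "permanova_terms": {r.term: r.p for r in perma if r.term != "Residual"},
        }

        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return PipelineResult(
            enrichment=enrichment, summary=summary, assimilation=records, top=top,
            venn_regions=regions, predators=predators, ordination=ordination,
            variance_explained=[float(v) for v in var_exp], permanova=perma,
            manifest=manifest,
        )
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
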