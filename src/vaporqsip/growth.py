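"""Growth rates and community-level growth summaries.

Converts per-replicate APE ¹⁸O into relative growth rates (RGR, per day,
assuming linear growth over the incubation) and computes the community
summaries of a vapor-qSIP experiment: growing richness and population share,
per-sample mean RGR, proportional ¹⁸O assimilation with top-assimilator
ranking, growing-set overlap between treatments, per-phylum relative change
in growing richness, and flagging of putatively predatory lineages.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .errors import (
    EmptySampleError,
    InvalidLabelError,
    UndefinedAssimilationError,
)

__all__ = [
    "PREDATORY_ORDERS",
    "relative_growth_rate",
    "absolute_abundances",
    "growing_fraction",
    "sample_mean_rgr",
    "sample_summary",
    "proportional_assimilation",
    "top_assimilators",
    "growing_sets",
    "treatment_overlap",
    "region_sum",
    "shared_count",
    "unique_count",
    "phylum_change",
    "flag_putative_predators",
]

#: Orders whose members are assigned a putatively predatory lifestyle.
PREDATORY_ORDERS = frozenset(
    o.lower()
    for o in (
        "Myxococcales",
        "Bdellovibrionales",
        "Vampirovibrionales",
        "Haliangiales",
        "Polyangiales",
    )
)


def relative_growth_rate(ape_taxon, ape_soil_water, days):
    """Per-day relative growth rate from taxon and soil-water APE.

    ``RGR = AFE_taxon / (AFE_soil_water · days)`` with atom percent excess
    converted to decimal atom fraction excess; the percent scale cancels, so
    APE inputs can be passed directly.  Assumes linear growth.
    """
    ape_w = np.asarray(ape_soil_water, dtype=float)
    if np.any(ape_w <= 0):
        raise InvalidLabelError("soil-water APE must be positive")
    if days <= 0:
        raise ValueError("incubation length must be positive")
    out = np.asarray(ape_taxon, dtype=float) / (ape_w * days)
    return float(out) if np.isscalar(ape_taxon) and np.isscalar(ape_soil_water) else out


def absolute_abundances(
    features: pd.DataFrame,
    fractions: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    labeled_only: bool = True,
) -> pd.DataFrame:
    """Per-sample taxon 16S copies (taxa × tubes).

    Relative abundance of a taxon in a sample is its reads summed over the
    retained fractions divided by all reads of the sample; multiplied by the
    ddPCR 16S copies accumulated over the same fractions.  Labeled tubes only
    by default (the tubes whose growth is quantified).
    """
    out = {}
    for tube, sub in fractions.groupby("tube_id", sort=True):
        if labeled_only and samples is not None and samples.loc[tube, "isotope"] != "18O":
            continue
        reads = features.loc[:, sub.index].sum(axis=1)
        total_reads = float(reads.sum())
        total_copies = float(sub["total_copies"].sum())
        if total_copies <= 0 or total_reads <= 0:
            raise EmptySampleError(f"sample {tube} has no copies or reads after filtering")
        out[tube] = reads / total_reads * total_copies
    return pd.DataFrame(out)


def growing_fraction(abundances: pd.Series, growing: pd.Series) -> float:
    """Percent of a sample's 16S copies belonging to growing taxa."""
    growing_taxa = growing.index[growing.astype(bool)]
    flags = abundances.index.isin(growing_taxa)
    total = float(abundances.sum())
    if total <= 0:
        return 0.0
    return 100.0 * float(abundances[flags].sum()) / total


def sample_mean_rgr(
    enrichment: pd.DataFrame,
    include_nongrowing: bool = False,
    days: float | None = None,
) -> pd.Series:
    """Unweighted mean taxon-level RGR per labeled tube.

    ``include_nongrowing=False`` averages growing taxa only (APE > 5);
    ``True`` averages every retained taxon with negative EAF clamped to 0,
    the whole-community variant.  Tubes with no qualifying taxa get NaN.
    """
    enr = enrichment.copy()
    d = days if days is not None else float(enr["incubation_days"].iloc[0]) if "incubation_days" in enr else 5.0
    ape = enr["ape"].clip(lower=0.0) if include_nongrowing else enr["ape"]
    enr["rgr"] = relative_growth_rate(
        ape.to_numpy(), enr["soil_water_ape"].to_numpy(), d
    )
    if not include_nongrowing:
        enr = enr[enr["growing"]]
    means = enr.groupby("tube_id")["rgr"].mean()
    return means.reindex(sorted(enrichment["tube_id"].unique()))


def sample_summary(
    enrichment: pd.DataFrame,
    abundances: pd.DataFrame,
    samples: pd.DataFrame,
    days: float | None = None,
) -> pd.DataFrame:
    """Per-labeled-sample growth summary.

    Columns: treatment, growing_richness, growing_pct (share of 16S copies in
    growing taxa), mean_rgr_growing, mean_rgr_all (non-growing included,
    negative EAF clamped to 0), total_copies.
    """
    enr = enrichment.merge(
        samples[["soil_water_ape", "incubation_days"]],
        left_on="tube_id", right_index=True,
    )
    mean_growing = sample_mean_rgr(enr, include_nongrowing=False, days=days)
    mean_all = sample_mean_rgr(enr, include_nongrowing=True, days=days)
    rows = []
    for tube in sorted(enr["tube_id"].unique()):
        sub = enr[enr["tube_id"] == tube]
        growing = sub.set_index("taxon_id")["growing"]
        abund = abundances[tube]
        rows.append(
            {
                "sample_id": tube,
                "treatment": samples.loc[tube, "treatment"],
                "growing_richness": int(growing.sum()),
                "growing_pct": growing_fraction(abund, growing),
                "mean_rgr_growing": mean_growing.get(tube, np.nan),
                "mean_rgr_all": mean_all.get(tube, np.nan),
                "total_copies": float(abund.sum()),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def proportional_assimilation(
    growing_abundances: pd.Series, rgrs: pd.Series
) -> pd.Series:
    """Share of whole-community growth attributable to each growing taxon.

    Growing-subset abundances are renormalised to sum to 1, multiplied by the
    taxon RGR, and divided by their sum, giving values in [0, 1] that sum to 1.
    """
    a = growing_abundances.astype(float)
    if len(a) == 0:
        raise UndefinedAssimilationError("no growing taxa in sample")
    total = float(a.sum())
    if total <= 0:
        raise UndefinedAssimilationError("growing abundances sum to zero")
    a = a / total
    w = a * rgrs.reindex(a.index).astype(float)
    s = float(w.sum())
    if s <= 0:
        raise UndefinedAssimilationError("all growth rates zero; assimilation undefined")
    return w / s


def assimilation_table(
    enrichment: pd.DataFrame,
    abundances: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample proportional-assimilation records with within-sample ranks."""
    rows = []
    for tube in sorted(enrichment["tube_id"].unique()):
        sub = enrichment[(enrichment["tube_id"] == tube) & enrichment["growing"]]
        if sub.empty:
            continue
        idx = sub["taxon_id"].to_numpy()
        abund = abundances.loc[idx, tube]
        rgr = pd.Series(
            relative_growth_rate(
                sub["ape"].to_numpy(),
                samples.loc[tube, "soil_water_ape"],
                samples.loc[tube, "incubation_days"],
            ),
            index=idx,
        )
        p = proportional_assimilation(abund, rgr)
        rank = p.rank(ascending=False, method="first").astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "taxon_id": idx,
                    "sample_id": tube,
                    "treatment": samples.loc[tube, "treatment"],
                    "rel_abund_growing": (abund / abund.sum()).to_numpy(),
                    "rgr": rgr.to_numpy(),
                    "proportional_assimilation": p.to_numpy(),
                    "rank": rank.to_numpy(),
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "taxon_id", "sample_id", "treatment", "rel_abund_growing",
                "rgr", "proportional_assimilation", "rank",
            ]
        )
    return pd.concat(rows, ignore_index=True)


def _agglomerated_label(lineage: pd.Series) -> str:
    """Genus label, falling back to family then phylum when unassigned."""
    for rank in ("genus", "family", "phylum"):
        name = str(lineage.get(rank, "") or "").strip()
        if name and name.upper() != "NA":
            return name
    return "unclassified"


def top_assimilators(
    records: pd.DataFrame,
    taxonomy: pd.DataFrame,
    n: int = 5,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Union of each sample's top-``n`` proportional assimilators.

    Ranking happens at taxon (ASV) level; a taxon qualifies only when growing
    in at least ``min_samples`` samples of its treatment.  Labels are
    agglomerated at genus level, with family then phylum as fallbacks for
    unassigned genera, after selection.
    """
    if records.empty:
        return pd.DataFrame(columns=list(records.columns) + ["label"])
    counts = records.groupby(["treatment", "taxon_id"])["sample_id"].nunique()
    ok = records.apply(
        lambda r: counts.loc[(r["treatment"], r["taxon_id"])] >= min_samples, axis=1
    )
    eligible = records[ok]
    picks = []
    for sample, sub in eligible.groupby("sample_id"):
        picks.append(sub.nlargest(n, "proportional_assimilation"))
    if not picks:
        return pd.DataFrame(columns=list(records.columns) + ["label"])
    out = pd.concat(picks, ignore_index=True)
    out["label"] = [
        _agglomerated_label(taxonomy.loc[t]) if t in taxonomy.index else "unclassified"
        for t in out["taxon_id"]
    ]
    return out.sort_values(
        ["sample_id", "proportional_assimilation"], ascending=[True, False]
    ).reset_index(drop=True)


def growing_sets(
    enrichment: pd.DataFrame, min_replicates: int = 2
) -> dict[str, set]:
    """Per-treatment sets of taxa growing in ≥ ``min_replicates`` replicates."""
    counts = (
        enrichment[enrichment["growing"]]
        .groupby(["treatment", "taxon_id"])["tube_id"]
        .nunique()
    )
    out: dict[str, set] = {t: set() for t in enrichment["treatment"].unique()}
    for (treatment, taxon), c in counts.items():
        if c >= min_replicates:
            out[treatment].add(taxon)
    return out


def treatment_overlap(sets: dict[str, set]) -> dict[frozenset, int]:
    """Venn region cardinalities of the treatments' growing sets.

    Returns a mapping from each non-empty combination of treatment names
    (frozenset) to the number of taxa growing in exactly those treatments.
    """
    names = sorted(sets)
    regions: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(set(), *(sets[c] for c in names if c not in combo))
            regions[frozenset(combo)] = len(inside - outside)
    return regions


def region_sum(regions: dict[frozenset, int], must_include, any_of=None) -> int:
    """Total taxa in regions containing all of ``must_include`` (and, when
    given, at least one of ``any_of``)."""
    must = set(must_include)
    any_set = set(any_of) if any_of is not None else None
    total = 0
    for combo, count in regions.items():
        if not must <= combo:
            continue
        if any_set is not None and not (combo & any_set):
            continue
        total += count
    return total


def shared_count(regions: dict[frozenset, int], a: str, b: str) -> int:
    """Taxa growing in both treatments ``a`` and ``b`` (any other overlap)."""
    return region_sum(regions, {a, b})


def unique_count(regions: dict[frozenset, int], a: str) -> int:
    """Taxa growing exclusively in treatment ``a``."""
    return regions.get(frozenset({a}), 0)


def phylum_change(
    growing_counts: pd.DataFrame,
    sample_treatments: pd.Series,
    reference: str,
    treatment: str,
) -> pd.DataFrame:
    """Relative change in growing richness per phylum between two treatments.

    ``growing_counts`` is phyla × samples (number of growing taxa).  Change is
    ``(mean_treatment − mean_reference)/mean_reference`` (0 = no change,
    1 = +100%).  Phyla with a zero reference mean get NaN and are flagged
    ``undefined`` rather than raising.
    """
    ref_samples = sample_treatments.index[sample_treatments == reference]
    trt_samples = sample_treatments.index[sample_treatments == treatment]
    if len(ref_samples) == 0:
        raise ValueError(f"reference treatment {reference!r} has no samples")
    ref_mean = growing_counts[ref_samples].mean(axis=1)
    trt_mean = growing_counts[trt_samples].mean(axis=1)
    undefined = ref_mean == 0
    change = (trt_mean - ref_mean) / ref_mean.where(~undefined)
    return pd.DataFrame(
        {
            "reference_mean": ref_mean,
            "treatment_mean": trt_mean,
            "relative_change": change,
            "undefined": undefined,
        }
    )


def flag_putative_predators(lineage) -> bool:
    """True when the lineage's order is one of the putatively predatory orders."""
    order = lineage.get("order", "") if hasattr(lineage, "get") else lineage
    return str(order or "").strip().lower() in PREDATORY_ORDERS
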