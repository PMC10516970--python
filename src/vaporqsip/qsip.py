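"""Core qSIP estimator: filtering, weighted-average densities, ¹⁸O enrichment.

The estimator turns fraction-resolved amplicon counts plus ddPCR totals into a
per-taxon, per-replicate excess atom fraction (EAF) of ¹⁸O:

* per-fraction taxon copies ``y_f = (reads_f,taxon / Σ_taxa reads_f) · total_copies_f``
* weighted average density (WAD) ``W = Σ_f density_f · y_f / Σ_f y_f``
* GC content inferred from the unlabeled WAD through the linear density–GC
  relation, giving light and maximally-labeled DNA molecular weights
* the labeled WAD shift is converted to a molecular-weight shift and scaled by
  the maximal ¹⁸O-induced shift to give the excess atom fraction:
  ``EAF = ((M_lab − M_light)/(M_heavymax − M_light)) · (1 − 0.002000429)``

APE ¹⁸O = 100·EAF; a taxon is *active* at APE > 0 and *growing* at APE > 5%,
the threshold that guards against between-tube density variation.

Tables are plain pandas objects: a feature table (taxa × fraction columns named
``tube:fractionIndex``), fraction metadata indexed by those column ids, and
sample metadata indexed by tube id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UncorrectableTubeError

__all__ = [
    "QsipConstants",
    "DEFAULT_CONSTANTS",
    "filter_fractions",
    "taxon_copies",
    "taxon_wad",
    "tube_wads",
    "tube_community_wad",
    "correct_wad_offset",
    "prevalence_filter",
    "gc_from_wad",
    "molecular_weights",
    "excess_atom_fraction",
    "enrich_all",
]

logger = logging.getLogger(__name__)

# fraction-metadata columns the estimator relies on
FRACTION_COLUMNS = ("tube_id", "fraction_index", "density", "total_copies", "total_read_pairs")


@dataclass(frozen=True)
class QsipConstants:
    """Physical constants of the density/GC/molecular-weight relations.

    Values follow the standard qSIP calibration: buoyant density is linear in
    GC fraction, DNA molecular weight is linear in GC, full ¹⁸O substitution of
    DNA oxygen raises the molecular weight by a fixed amount, and natural ¹⁸O
    abundance is subtracted so an unlabeled taxon has EAF 0.
    """

    density_gc_slope: float = 0.083506  # g/mL per GC fraction
    density_gc_intercept: float = 1.646057  # g/mL at GC = 0
    mw_gc_slope: float = 0.496  # g/mol per GC fraction
    mw_intercept: float = 307.691  # g/mol at GC = 0
    mw_18O_max_shift: float = 12.07747  # g/mol, fully ¹⁸O-substituted
    nat_abund_18O: float = 0.002000429  # atom fraction

    @property
    def max_eaf(self) -> float:
        """Largest attainable excess atom fraction, 1 − natural abundance."""
        return 1.0 - self.nat_abund_18O


DEFAULT_CONSTANTS = QsipConstants()


def filter_fractions(
    fractions: pd.DataFrame,
    density_min: float = 1.614,
    density_max: float = 1.753,
    min_read_pairs: int = 2000,
) -> pd.DataFrame:
    """Keep fractions inside the density window with enough sequencing yield.

    The density window is inclusive on both ends; the read-pair cut is strict
    (``> min_read_pairs``), so a fraction with exactly ``min_read_pairs`` reads
    is dropped.  Tubes left with fewer than 4 retained fractions are logged;
    the prevalence filter deals with them downstream.
    """
    dens = fractions["density"].to_numpy(dtype=float)
    if not np.all(np.isfinite(dens)):
        raise ValueError("non-finite densities in fraction metadata")
    keep = (
        (fractions["density"] >= density_min)
        & (fractions["density"] <= density_max)
        & (fractions["total_read_pairs"] > min_read_pairs)
    )
    out = fractions.loc[keep]
    counts = out.groupby("tube_id").size()
    for tube in fractions["tube_id"].unique():
        n = int(counts.get(tube, 0))
        if n < 4:
            logger.warning("tube %s retains only %d fractions after filtering", tube, n)
    return out


def taxon_copies(features: pd.DataFrame, fractions: pd.DataFrame) -> pd.DataFrame:
    """Per-fraction absolute copies per taxon (taxa × retained fractions).

    Read proportions within each fraction are scaled by that fraction's ddPCR
    total; fractions with zero reads contribute zero copies for every taxon.
    """
    cols = fractions.index
    sub = features.loc[:, cols]
    read_sums = sub.sum(axis=0)
    scale = fractions["total_copies"].where(read_sums > 0, 0.0)
    denom = read_sums.replace(0, 1.0)
    return sub.div(denom, axis=1).mul(scale, axis=1)


def taxon_wad(densities, copies) -> tuple[float, int]:
    """Weighted average density of one taxon in one tube.

    Parameters are aligned per-fraction vectors of densities (g/mL) and
    absolute taxon copies.  Returns ``(wad, n_fractions_present)`` where
    presence means nonzero copies; an absent taxon returns ``(nan, 0)``.
    """
    d = np.asarray(densities, dtype=float)
    y = np.asarray(copies, dtype=float)
    if d.shape != y.shape:
        raise ValueError("densities and copies must align")
    total = y.sum()
    n_present = int(np.count_nonzero(y > 0))
    if total <= 0:
        return float("nan"), 0
    return float((d * y).sum() / total), n_present


def tube_wads(
    features: pd.DataFrame, fractions: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """WADs of every taxon in every tube (vectorised :func:`taxon_wad`).

    Returns ``(wads, presence)`` — two taxa × tube frames, WAD being NaN where
    a taxon is absent from a tube, and presence counting fractions with
    nonzero reads.
    """
    copies = taxon_copies(features, fractions)
    wads = {}
    presence = {}
    for tube, sub in fractions.groupby("tube_id", sort=True):
        y = copies.loc[:, sub.index]
        d = sub["density"]
        total = y.sum(axis=1)
        num = y.mul(d, axis=1).sum(axis=1)
        wads[tube] = num.div(total.where(total > 0))
        presence[tube] = (y > 0).sum(axis=1)
    return pd.DataFrame(wads), pd.DataFrame(presence)


def tube_community_wad(features: pd.DataFrame, fractions: pd.DataFrame) -> pd.Series:
    """Copy-weighted mean density of the whole community, per tube."""
    out = {}
    for tube, sub in fractions.groupby("tube_id", sort=True):
        w = sub["total_copies"].to_numpy(dtype=float)
        d = sub["density"].to_numpy(dtype=float)
        out[tube] = float((d * w).sum() / w.sum()) if w.sum() > 0 else float("nan")
    return pd.Series(out, name="community_wad")


def correct_wad_offset(
    fractions: pd.DataFrame,
    samples: pd.DataFrame,
    flagged_tube_ids,
    features: pd.DataFrame,
    group_cols=("treatment", "isotope"),
) -> pd.DataFrame:
    """Subtract the tube-level density offset of tubes that lost fractions.

    When low-density fractions of a tube are lost during fractionation its
    community WAD is biased heavy.  For each explicitly flagged tube, the
    offset is its community WAD minus the mean community WAD of the unflagged
    tubes in the same (treatment × isotope) group; the offset is subtracted
    from every fraction density of the flagged tube.

    Returns a copy of ``fractions`` with adjusted densities.
    """
    flagged = set(flagged_tube_ids)
    if not flagged:
        return fractions
    comm = tube_community_wad(features, fractions)
    out = fractions.copy()
    for tube in sorted(flagged):
        group = tuple(samples.loc[tube, c] for c in group_cols)
        members = [
            t
            for t in samples.index
            if t not in flagged
            and tuple(samples.loc[t, c] for c in group_cols) == group
            and t in comm.index
            and np.isfinite(comm[t])
        ]
        if not members:
            raise UncorrectableTubeError(
                f"tube {tube} has no unflagged reference tubes in group {group}"
            )
        offset = comm[tube] - float(np.mean([comm[t] for t in members]))
        mask = out["tube_id"] == tube
        out.loc[mask, "density"] = out.loc[mask, "density"] - offset
        logger.info("tube %s density offset corrected by %.5f g/mL", tube, offset)
    return out


def prevalence_filter(
    features: pd.DataFrame,
    fractions: pd.DataFrame,
    samples: pd.DataFrame,
    min_fractions: int = 4,
    min_replicates: int = 2,
    labeled_only: bool = True,
) -> tuple[dict, pd.Series]:
    """Per-treatment sets of taxa frequent enough for qSIP.

    A taxon is retained for a treatment when it has reads in at least
    ``min_fractions`` retained fractions in each of at least ``min_replicates``
    replicate tubes of that treatment.  Replicates are counted over labeled
    tubes by default (the tubes whose enrichment is estimated).

    Returns ``(retained, coverage)``: treatment → taxon set, and the fraction
    of read pairs the retained taxa account for per treatment.
    """
    retained: dict[str, set] = {}
    coverage = {}
    for treatment, tubes in samples.groupby("treatment", sort=True).groups.items():
        tubes = [
            t for t in tubes
            if (not labeled_only) or samples.loc[t, "isotope"] == "18O"
        ]
        qualifying = pd.Series(0, index=features.index)
        total_reads = 0.0
        kept_reads = pd.Series(0.0, index=features.index)
        for tube in tubes:
            cols = fractions.index[fractions["tube_id"] == tube]
            if len(cols) == 0:
                continue
            sub = features.loc[:, cols]
            n_present = (sub > 0).sum(axis=1)
            qualifying += (n_present >= min_fractions).astype(int)
            kept_reads += sub.sum(axis=1)
            total_reads += float(sub.to_numpy().sum())
        keep = qualifying >= min_replicates
        retained[treatment] = set(features.index[keep])
        coverage[treatment] = (
            float(kept_reads[keep].sum() / total_reads) if total_reads > 0 else 0.0
        )
    return retained, pd.Series(coverage, name="read_pair_coverage")


def gc_from_wad(w_light, constants: QsipConstants = DEFAULT_CONSTANTS):
    """GC fraction implied by an unlabeled WAD via the linear density relation.

    Values are clamped to [0, 1]; clamping is logged, not an error, because
    density noise can push the linear inverse slightly out of range.
    """
    w = np.asarray(w_light, dtype=float)
    gc = (w - constants.density_gc_intercept) / constants.density_gc_slope
    n_clamped = int(np.sum((gc < 0) | (gc > 1)))
    if n_clamped:
        logger.debug("gc_from_wad clamped %d value(s) to [0, 1]", n_clamped)
    gc = np.clip(gc, 0.0, 1.0)
    return float(gc) if np.isscalar(w_light) else gc


def molecular_weights(gc, constants: QsipConstants = DEFAULT_CONSTANTS):
    """Light and maximally ¹⁸O-labeled DNA molecular weights for a GC content."""
    g = np.asarray(gc, dtype=float)
    m_light = constants.mw_gc_slope * g + constants.mw_intercept
    m_heavymax = m_light + constants.mw_18O_max_shift
    if np.isscalar(gc):
        return float(m_light), float(m_heavymax)
    return m_light, m_heavymax


def excess_atom_fraction(w_light, w_lab, constants: QsipConstants = DEFAULT_CONSTANTS):
    """¹⁸O excess atom fraction from unlabeled and labeled WADs.

    ``M_lab = M_light · (W_lab / W_light)``;
    ``EAF = ((M_lab − M_light)/(M_heavymax − M_light)) · (1 − nat_abund)``.
    Negative values (labeled WAD lighter than the reference) are returned
    as-is; downstream summaries clamp where appropriate.
    """
    gc = gc_from_wad(w_light, constants)
    m_light, m_heavymax = molecular_weights(gc, constants)
    m_lab = m_light * (np.asarray(w_lab, dtype=float) / np.asarray(w_light, dtype=float))
    eaf = (m_lab - m_light) / (m_heavymax - m_light) * constants.max_eaf
    return float(eaf) if np.isscalar(w_lab) and np.isscalar(w_light) else eaf


def enrich_all(
    features: pd.DataFrame,
    fractions: pd.DataFrame,
    samples: pd.DataFrame,
    constants: QsipConstants = DEFAULT_CONSTANTS,
    ape_growing_threshold: float = 5.0,
    ape_active_threshold: float = 0.0,
    retained: dict | None = None,
) -> pd.DataFrame:
    """Per-taxon, per-labeled-replicate enrichment table.

    For each treatment the unlabeled reference WAD of a taxon is the mean of
    its WADs across the treatment's natural-abundance tubes; taxa missing from
    those fall back to the global unlabeled mean, and taxa missing from every
    unlabeled tube are excluded (logged).  One row is produced per retained
    taxon × labeled tube where the taxon is present.

    Parameters
    ----------
    retained
        Optional treatment → taxon-set mapping from :func:`prevalence_filter`;
        ``None`` means all taxa are eligible.

    Returns
    -------
    pandas.DataFrame
        Columns: taxon_id, treatment, tube_id, replicate, w_light, w_lab, gc,
        m_light, m_lab, m_heavymax, eaf, ape, active, growing,
        n_fractions_present.
    """
    wads, presence = tube_wads(features, fractions)
    labeled = samples.index[samples["isotope"] == "18O"]
    unlabeled = samples.index[samples["isotope"] != "18O"]
    if len(labeled) == 0 or len(unlabeled) == 0:
        raise ValueError("need at least one labeled and one unlabeled tube")

    unlabeled_in = {c for c in wads.columns if c in set(unlabeled)}
    global_ref = wads[sorted(unlabeled_in)].mean(axis=1)

    rows = []
    for treatment, tubes in samples.groupby("treatment", sort=True).groups.items():
        lab_tubes = [t for t in tubes if t in set(labeled) and t in wads.columns]
        unlab_tubes = [t for t in tubes if t in unlabeled_in]
        treat_ref = (
            wads[unlab_tubes].mean(axis=1) if unlab_tubes else
            pd.Series(np.nan, index=wads.index)
        )
        w_light = treat_ref.fillna(global_ref)
        n_excluded = int(w_light.isna().sum())
        if n_excluded:
            logger.info(
                "treatment %s: %d taxa lack any unlabeled reference WAD and are excluded",
                treatment, n_excluded,
            )
        eligible = retained.get(treatment, set()) if retained is not None else None
        for tube in lab_tubes:
            w_lab = wads[tube]
            ok = w_lab.notna() & w_light.notna()
            if eligible is not None:
                ok &= wads.index.isin(list(eligible))
            idx = wads.index[ok]
            if len(idx) == 0:
                continue
            wl = w_light[idx].to_numpy()
            wb = w_lab[idx].to_numpy()
            gc = gc_from_wad(wl, constants)
            m_light, m_heavymax = molecular_weights(gc, constants)
            m_lab = m_light * (wb / wl)
            eaf = (m_lab - m_light) / (m_heavymax - m_light) * constants.max_eaf
            ape = 100.0 * eaf
            frame = pd.DataFrame(
                {
                    "taxon_id": idx,
                    "treatment": treatment,
                    "tube_id": tube,
                    "replicate": samples.loc[tube, "replicate"],
                    "w_light": wl,
                    "w_lab": wb,
                    "gc": gc,
                    "m_light": m_light,
                    "m_lab": m_lab,
                    "m_heavymax": m_heavymax,
                    "eaf": eaf,
                    "ape": ape,
                    "active": ape > ape_active_threshold,
                    "growing": ape > ape_growing_threshold,
                    "n_fractions_present": presence.loc[idx, tube].to_numpy(),
                }
            )
            rows.append(frame)
    if not rows:
        return pd.DataFrame(
            columns=[
                "taxon_id", "treatment", "tube_id", "replicate", "w_light",
                "w_lab", "gc", "m_light", "m_lab", "m_heavymax", "eaf", "ape",
                "active", "growing", "n_fractions_present",
            ]
        )
    return pd.concat(rows, ignore_index=True)
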