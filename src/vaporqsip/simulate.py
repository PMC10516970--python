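"""Synthetic vapor-qSIP gradient data with known ground truth.

The generator emulates the study design end-to-end: a shared pool of taxa
(lineage, GC content, lognormal base abundances), four treatments in a full
2 × 2 factorial (drought × climate) with four replicates each, one labeled
(¹⁸O) and one natural-abundance (¹⁶O) tube per replicate, and 24 density
fractions per tube.  Each taxon's DNA spreads over the density grid as a
Gaussian centered on its weighted average density — the unlabeled WAD for
natural-abundance tubes, the EAF-shifted WAD for labeled tubes — and reads are
drawn multinomially from the resulting copy proportions.  Scenario presets set
the abundance-weighted share of the community that is growing (ambient 35%,
drought 4%, future climate 45%, future climate + drought 9%), mirroring the
magnitude of drought effects observed in montane grassland soils.

Ground truth (per-taxon EAF and RGR, per-treatment growing share, soil-water
enrichment) is returned alongside so every downstream estimator can be tested
for parameter recovery.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ScenarioError
from .qsip import DEFAULT_CONSTANTS, QsipConstants, gc_from_wad

__all__ = [
    "TaxonProfile",
    "ExperimentDesign",
    "GroundTruth",
    "SimulatedExperiment",
    "SCENARIO_GROWING_SHARE",
    "TREATMENT_FACTORS",
    "simulate_community",
    "wad_shift_from_eaf",
    "simulate_tube",
    "simulate_experiment",
]

#: Abundance-weighted share of 16S copies belonging to growing taxa, by scenario.
SCENARIO_GROWING_SHARE = {
    "ambient": 0.35,
    "drought": 0.04,
    "future": 0.45,
    "future_drought": 0.09,
}

#: Treatment name → (drought yes/no, climate ambient/future).
TREATMENT_FACTORS = {
    "ambient": ("no", "ambient"),
    "drought": ("yes", "ambient"),
    "future": ("no", "future"),
    "future_drought": ("yes", "future"),
}

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

# (phylum, class, order, family, genus) candidates with sampling weights;
# genus "" means unassigned, exercising the genus→family→phylum fallback.
# The pool includes the putatively predatory orders so predator flagging has
# positives to find.
_LINEAGES = [
    (8, ("Actinobacteriota", "Actinobacteria", "Streptomycetales", "Streptomycetaceae", "Streptomyces")),
    (6, ("Actinobacteriota", "Actinobacteria", "Propionibacteriales", "Nocardioidaceae", "Marmoricola")),
    (6, ("Actinobacteriota", "Actinobacteria", "Mycobacteriales", "Nocardiaceae", "Rhodococcus")),
    (5, ("Actinobacteriota", "Actinobacteria", "Micrococcales", "Intrasporangiaceae", "Oryzihumus")),
    (4, ("Actinobacteriota", "Thermoleophilia", "Solirubrobacterales", "Solirubrobacteraceae", "")),
    (10, ("Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Xanthobacteraceae", "Bradyrhizobium")),
    (7, ("Proteobacteria", "Gammaproteobacteria", "Burkholderiales", "Oxalobacteraceae", "Pseudoduganella")),
    (5, ("Proteobacteria", "Gammaproteobacteria", "Burkholderiales", "Comamonadaceae", "")),
    (4, ("Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae", "Sphingomonas")),
    (8, ("Acidobacteriota", "Vicinamibacteria", "Vicinamibacterales", "Vicinamibacteraceae", "")),
    (5, ("Acidobacteriota", "Blastocatellia", "Pyrinomonadales", "Pyrinomonadaceae", "RB41")),
    (6, ("Bacteroidota", "Bacteroidia", "Sphingobacteriales", "env.OPS 17", "")),
    (5, ("Bacteroidota", "Bacteroidia", "Chitinophagales", "Chitinophagaceae", "Flavisolibacter")),
    (4, ("Planctomycetota", "Planctomycetes", "Pirellulales", "Pirellulaceae", "")),
    (4, ("Verrucomicrobiota", "Verrucomicrobiae", "Chthoniobacterales", "Chthoniobacteraceae", "Candidatus Udaeobacter")),
    (3, ("Myxococcota", "Myxococcia", "Myxococcales", "Myxococcaceae", "Corallococcus")),
    (3, ("Myxococcota", "Polyangia", "Haliangiales", "Haliangiaceae", "Haliangium")),
    (2, ("Myxococcota", "Polyangia", "Polyangiales", "Polyangiaceae", "")),
    (2, ("Bdellovibrionota", "Bdellovibrionia", "Bdellovibrionales", "Bdellovibrionaceae", "Bdellovibrio")),
    (3, ("Crenarchaeota", "Nitrososphaeria", "Nitrososphaerales", "Nitrososphaeraceae", "")),
    (2, ("Latescibacterota", "Latescibacteria", "Latescibacterales", "Latescibacteraceae", "")),
]


@dataclass(frozen=True)
class TaxonProfile:
    """One synthetic taxon with its latent ground truth."""

    taxon_id: str
    lineage: tuple  # 7 ranks, domain … species ("" where unassigned)
    gc: float  # GC fraction in [0, 1]
    base_abundance: float  # 16S copies per tube, > 0
    w_light: float  # unlabeled WAD, g/mL (GC relation + taxon-level noise)
    true_eaf: float  # ¹⁸O excess atom fraction in [0, 0.998]
    soil_water_afe: float = 0.593  # atom fraction excess of the water pool

    @property
    def growing(self) -> bool:
        """True when the latent APE exceeds the 5% growing threshold."""
        return 100.0 * self.true_eaf > 5.0


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout and noise model of a synthetic experiment.

    Defaults follow the study conditions: 2 × 2 factorial, four replicates,
    labeled + natural-abundance tube per replicate, 24 fractions of a
    1.60–1.78 g/mL grid, five-day incubation, soil-water enrichment drawn
    uniformly in 55–64 atom% per treatment.
    """

    treatments: tuple = tuple(TREATMENT_FACTORS)
    n_replicates: int = 4
    n_taxa: int = 200
    n_fractions: int = 24
    density_min: float = 1.60
    density_max: float = 1.78
    reads_per_tube: int = 50_000
    incubation_days: float = 5.0
    sigma_d: float = 0.006  # within-tube density spread per taxon, g/mL
    density_jitter_sd: float = 0.0005  # refractometer noise, g/mL
    ddpcr_noise_sd: float = 0.1  # lognormal sigma on fraction totals
    wlight_noise_sd: float = 0.002  # taxon deviation from the GC line, g/mL
    abundance_sigma: float = 1.3  # lognormal sigma of base abundances
    soil_water_ape: dict | None = None  # treatment → atom% excess; None = draw
    seed: int = 0
    exact_reads: bool = False  # expected (float) reads instead of multinomial
    deposition: str = "cdf"  # "cdf" | "moment" (first-moment preserving)
    drop_low_fractions: dict = field(default_factory=dict)  # tube_id → n dropped

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates for the prevalence filter")
        if self.n_fractions < 4:
            raise ValueError("need at least 4 fractions")

    @property
    def noiseless(self) -> "ExperimentDesign":
        """Copy of the design with every noise source switched off."""
        from dataclasses import replace

        return replace(
            self,
            density_jitter_sd=0.0,
            ddpcr_noise_sd=0.0,
            wlight_noise_sd=0.0,
            exact_reads=True,
            deposition="moment",
        )


@dataclass
class GroundTruth:
    """Latent quantities of a simulated experiment, for recovery tests."""

    taxa: pd.DataFrame  # per taxon × treatment: true_eaf, true_rgr, growing
    treatment_growing_share: pd.Series  # realized % of copies growing
    soil_water_ape: pd.Series  # atom% excess per treatment
    abundances: pd.Series  # base 16S copies per taxon (identical across tubes)
    incubation_days: float


@dataclass
class SimulatedExperiment:
    """The four pipeline input tables plus ground truth."""

    features: pd.DataFrame
    fractions: pd.DataFrame
    samples: pd.DataFrame
    taxonomy: pd.DataFrame
    truth: GroundTruth


def _stable_seed(master: int, tag: str) -> int:
    """Deterministic sub-seed below 2**31 from a master seed and a label."""
    return zlib.crc32(f"{master}:{tag}".encode()) & 0x7FFFFFFF


def wad_shift_from_eaf(
    gc: float,
    w_light: float,
    eaf,
    constants: QsipConstants = DEFAULT_CONSTANTS,
):
    """Labeled WAD produced by a given excess atom fraction (forward model).

    Exact inverse of :func:`vaporqsip.qsip.excess_atom_fraction` when ``gc``
    equals the density-implied GC of ``w_light``.
    """
    e = np.asarray(eaf, dtype=float)
    if np.any((e < 0) | (e > 0.998)):
        raise ValueError("eaf outside [0, 0.998]")
    m_light = constants.mw_gc_slope * np.asarray(gc, dtype=float) + constants.mw_intercept
    m_lab = m_light + (e / constants.max_eaf) * constants.mw_18O_max_shift
    out = np.asarray(w_light, dtype=float) * (m_lab / m_light)
    return float(out) if np.isscalar(eaf) else out


def _make_pool(n_taxa: int, rng: np.random.Generator, design: ExperimentDesign):
    """Shared taxon pool: ids, lineages, GC, abundances, unlabeled WADs."""
    if n_taxa < 10:
        raise ValueError("need at least 10 taxa")
    weights = np.array([w for w, _ in _LINEAGES], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(_LINEAGES), size=n_taxa, p=weights)
    lineages = []
    for i in picks:
        phylum, class_, order, family, genus = _LINEAGES[i][1]
        domain = "Archaea" if phylum == "Crenarchaeota" else "Bacteria"
        lineages.append((domain, phylum, class_, order, family, genus, ""))
    gc = rng.uniform(0.3, 0.7, size=n_taxa)
    abundance = rng.lognormal(mean=np.log(1e6), sigma=design.abundance_sigma, size=n_taxa)
    w_light = (
        DEFAULT_CONSTANTS.density_gc_intercept
        + DEFAULT_CONSTANTS.density_gc_slope * gc
        + rng.normal(0.0, design.wlight_noise_sd, size=n_taxa)
    )
    ids = [f"ASV_{i + 1:04d}" for i in range(n_taxa)]
    return ids, lineages, gc, abundance, w_light


def _assign_growth(
    abundance: np.ndarray,
    target_share: float,
    soil_water_afe: float,
    rng: np.random.Generator,
    active_nongrowing_frac: float = 0.3,
) -> np.ndarray:
    """Per-taxon true EAF hitting an abundance-weighted growing share.

    Taxa are visited in random order and flagged growing while their summed
    abundance share stays at or below the target, so the realized share tracks
    the preset closely regardless of how skewed the abundance distribution is.
    Growing taxa draw EAF from a Beta(2, 4) scaled to (0.06, soil-water AFE):
    safely above the 5% APE threshold and capped by the water pool enrichment
    (fully labeled new DNA).  A fraction of the non-growing taxa is active but
    below threshold (EAF uniform on (0, 0.04)); the rest are at 0.
    """
    n = abundance.size
    shares = abundance / abundance.sum()
    eaf = np.zeros(n)
    if target_share > 0:
        order = rng.permutation(n)
        cum = 0.0
        growing = np.zeros(n, dtype=bool)
        for i in order:
            if cum + shares[i] <= target_share:
                growing[i] = True
                cum += shares[i]
        lower, upper = 0.06, min(0.998, soil_water_afe)
        if upper <= lower:
            raise ValueError("soil-water AFE too low to host growing taxa")
        k = int(growing.sum())
        eaf[growing] = lower + rng.beta(2.0, 4.0, size=k) * (upper - lower)
    else:
        growing = np.zeros(n, dtype=bool)
    nong = np.flatnonzero(~growing)
    active = nong[rng.random(nong.size) < active_nongrowing_frac]
    eaf[active] = rng.uniform(0.0, 0.04, size=active.size)
    return eaf


def simulate_community(
    n_taxa: int,
    scenario: str,
    seed: int,
    soil_water_afe: float = 0.593,
    design: ExperimentDesign | None = None,
) -> list[TaxonProfile]:
    """Taxon profiles for one scenario (one treatment's ground truth)."""
    if scenario not in SCENARIO_GROWING_SHARE:
        raise ScenarioError(
            f"unknown scenario {scenario!r}; choose from {sorted(SCENARIO_GROWING_SHARE)}"
        )
    design = design or ExperimentDesign(n_taxa=n_taxa, seed=seed)
    rng = np.random.default_rng(_stable_seed(seed, f"community:{scenario}"))
    ids, lineages, gc, abundance, w_light = _make_pool(n_taxa, rng, design)
    eaf = _assign_growth(abundance, SCENARIO_GROWING_SHARE[scenario], soil_water_afe, rng)
    return [
        TaxonProfile(ids[i], lineages[i], float(gc[i]), float(abundance[i]),
                     float(w_light[i]), float(eaf[i]), soil_water_afe)
        for i in range(n_taxa)
    ]


def _gaussian_bin_masses(
    centers: np.ndarray, mu: np.ndarray, sigma: float, edges: np.ndarray,
    scheme: str,
) -> np.ndarray:
    """Distribute unit Gaussian mass over the fraction grid, per taxon.

    ``cdf``: mass of bin i is the Gaussian probability between its edges, with
    the tails folded into the end bins (conserves mass; the binned first
    moment carries O(h²) discretization error).

    ``moment``: hat-function (linear) deposition onto bin centers; the binned
    first moment equals ``mu`` exactly for mass inside the grid, which is what
    noiseless recovery tests need.
    """
    mu = mu[:, None]
    if scheme == "cdf":
        cdf = norm.cdf((edges[None, :] - mu) / sigma)
        mass = np.diff(cdf, axis=1)
        mass[:, 0] += cdf[:, 0]
        mass[:, -1] += 1.0 - cdf[:, -1]
        return mass
    if scheme == "moment":
        c = centers[None, :]
        z = (centers[None, :] - mu) / sigma
        # partial moments of the Gaussian between consecutive centers:
        # P_i = P(c_i < X < c_{i+1}); M_i = E[X; c_i < X < c_{i+1}]
        cdf = norm.cdf(z)
        pdf = norm.pdf(z)
        P = np.diff(cdf, axis=1)
        M = mu * P - sigma * np.diff(pdf, axis=1)
        h = np.diff(centers)
        n = centers.size
        mass = np.zeros((mu.size, n))
        # interval [c_i, c_{i+1}] splits between centers i and i+1 linearly
        frac_up = (M - centers[:-1][None, :] * P) / h[None, :]
        mass[:, :-1] += P - frac_up
        mass[:, 1:] += frac_up
        # tails collapse onto the end centers
        mass[:, 0] += cdf[:, 0]
        mass[:, -1] += 1.0 - cdf[:, -1]
        return mass
    raise ValueError(f"unknown deposition scheme {scheme!r}")


def simulate_tube(
    profiles: list[TaxonProfile],
    isotope: str,
    design: ExperimentDesign,
    tube_seed: int,
    tube_id: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One gradient tube: feature-table block and fraction metadata.

    Each taxon's DNA mass spreads as a Gaussian (sd ``sigma_d``) centered on
    its tube WAD — ``w_light`` for natural-abundance tubes, the EAF-shifted
    WAD for labeled ones.  Per-fraction copies are abundance × bin mass; reads
    are multinomial over the tube's copy proportions; ddPCR totals get
    lognormal noise and densities Gaussian jitter.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    rng = np.random.default_rng(tube_seed)
    edges = np.linspace(design.density_min, design.density_max, design.n_fractions + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_width = edges[1] - edges[0]
    if bin_width > 2 * design.sigma_d:
        import warnings

        warnings.warn(
            f"density grid too coarse for sigma_d={design.sigma_d} "
            f"(bin width {bin_width:.4f} g/mL)",
            stacklevel=2,
        )
    w_light = np.array([p.w_light for p in profiles])
    if isotope == "18O":
        eaf = np.array([p.true_eaf for p in profiles])
        mu = wad_shift_from_eaf(gc_from_wad(w_light), w_light, eaf)
    else:
        mu = w_light
    mass = _gaussian_bin_masses(centers, mu, design.sigma_d, edges, design.deposition)
    abundance = np.array([p.base_abundance for p in profiles])
    copies = abundance[:, None] * mass
    col_true = copies.sum(axis=0)

    if design.ddpcr_noise_sd > 0:
        ddpcr = col_true * np.exp(rng.normal(0.0, design.ddpcr_noise_sd, size=col_true.size))
    else:
        ddpcr = col_true.copy()

    total = copies.sum()
    p = (copies / total).ravel()
    if design.exact_reads:
        reads = (design.reads_per_tube * p).reshape(copies.shape)
    else:
        reads = rng.multinomial(design.reads_per_tube, p).reshape(copies.shape).astype(float)
    read_totals = reads.sum(axis=0)

    dens = centers + (
        rng.normal(0.0, design.density_jitter_sd, size=centers.size)
        if design.density_jitter_sd > 0
        else 0.0
    )

    frac_ids = [f"{tube_id}:{i + 1}" for i in range(design.n_fractions)]
    features = pd.DataFrame(reads, index=[p_.taxon_id for p_ in profiles], columns=frac_ids)
    fractions = pd.DataFrame(
        {
            "tube_id": tube_id,
            "fraction_index": np.arange(1, design.n_fractions + 1),
            "density": dens,
            "total_copies": ddpcr,
            "total_read_pairs": read_totals,
        },
        index=pd.Index(frac_ids, name="fraction_id"),
    )
    n_drop = design.drop_low_fractions.get(tube_id, 0)
    if n_drop:
        dropped = frac_ids[:n_drop]
        features = features.drop(columns=dropped)
        fractions = fractions.drop(index=dropped)
    return features, fractions


def simulate_experiment(design: ExperimentDesign) -> SimulatedExperiment:
    """Full factorial synthetic experiment in the pipeline's input formats."""
    pool_rng = np.random.default_rng(_stable_seed(design.seed, "pool"))
    ids, lineages, gc, abundance, w_light = _make_pool(design.n_taxa, pool_rng, design)

    ape_rng = np.random.default_rng(_stable_seed(design.seed, "soil_water"))
    soil_ape = {}
    for t in design.treatments:
        if design.soil_water_ape and t in design.soil_water_ape:
            soil_ape[t] = float(design.soil_water_ape[t])
        else:
            soil_ape[t] = float(ape_rng.uniform(55.0, 64.0))

    truth_rows = []
    share = {}
    profiles_by_treatment = {}
    for t in design.treatments:
        afe = soil_ape[t] / 100.0
        rng = np.random.default_rng(_stable_seed(design.seed, f"growth:{t}"))
        eaf = _assign_growth(abundance, SCENARIO_GROWING_SHARE[t], afe, rng)
        profiles_by_treatment[t] = [
            TaxonProfile(ids[i], lineages[i], float(gc[i]), float(abundance[i]),
                         float(w_light[i]), float(eaf[i]), afe)
            for i in range(design.n_taxa)
        ]
        growing = 100.0 * eaf > 5.0
        share[t] = 100.0 * abundance[growing].sum() / abundance.sum()
        truth_rows.append(
            pd.DataFrame(
                {
                    "taxon_id": ids,
                    "treatment": t,
                    "true_eaf": eaf,
                    "true_rgr": eaf / (afe * design.incubation_days),
                    "growing": growing,
                }
            )
        )

    feature_blocks = []
    fraction_blocks = []
    sample_rows = []
    for t in design.treatments:
        drought, climate = TREATMENT_FACTORS[t]
        for rep in range(1, design.n_replicates + 1):
            for iso in ("18O", "16O"):
                tube_id = f"{t}_r{rep}_{iso}"
                feats, fracs = simulate_tube(
                    profiles_by_treatment[t], iso, design,
                    _stable_seed(design.seed, f"tube:{tube_id}"), tube_id,
                )
                feature_blocks.append(feats)
                fraction_blocks.append(fracs)
                sample_rows.append(
                    {
                        "tube_id": tube_id,
                        "treatment": t,
                        "drought": drought,
                        "climate": climate,
                        "replicate": rep,
                        "isotope": iso,
                        "incubation_days": design.incubation_days,
                        "soil_water_ape": soil_ape[t],
                    }
                )

    features = pd.concat(feature_blocks, axis=1)
    features.index.name = "taxon_id"
    fractions = pd.concat(fraction_blocks, axis=0)
    samples = pd.DataFrame(sample_rows).set_index("tube_id")
    taxonomy = pd.DataFrame(lineages, index=pd.Index(ids, name="taxon_id"), columns=RANKS)
    truth = GroundTruth(
        taxa=pd.concat(truth_rows, ignore_index=True),
        treatment_growing_share=pd.Series(share, name="growing_share_pct"),
        soil_water_ape=pd.Series(soil_ape, name="soil_water_ape"),
        abundances=pd.Series(abundance, index=ids, name="base_abundance"),
        incubation_days=design.incubation_days,
    )
    return SimulatedExperiment(features, fractions, samples, taxonomy, truth)
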