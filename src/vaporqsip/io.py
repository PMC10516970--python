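"""Reading, validating and writing the pipeline's tabular interchange files.

The canonical formats are tab-delimited UTF-8 TSV for tables and JSON for
nested results.  Feature-table columns are fraction ids ``tubeID:fractionIndex``;
densities live in the fraction metadata, never in column names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .simulate import RANKS, SimulatedExperiment

__all__ = [
    "read_features",
    "read_fractions",
    "read_samples",
    "read_taxonomy",
    "read_calibration",
    "load_inputs",
    "write_tsv",
    "write_experiment",
]

FRACTION_SCHEMA = ["fraction_id", "tube_id", "fraction_index", "density",
                   "total_copies", "total_read_pairs"]
SAMPLE_SCHEMA = ["tube_id", "treatment", "drought", "climate", "replicate",
                 "isotope", "incubation_days", "soil_water_ape"]
CALIBRATION_SCHEMA = ["group", "time_h", "atom_pct_18O"]


def _read(path, index_col, required, name):
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{name} file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype={index_col: str})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{name} file {path} is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} file {path} missing column(s): {missing}")
    if df[index_col].duplicated().any():
        dups = df.loc[df[index_col].duplicated(), index_col].tolist()
        raise SchemaError(f"{name} file {path} has duplicate ids: {dups[:5]}")
    return df.set_index(index_col)


def read_features(path) -> pd.DataFrame:
    """Feature table: rows = taxa, columns = ``tube:fraction`` ids, values = reads."""
    df = _read(path, "taxon_id", ["taxon_id"], "feature table")
    return df.astype(float)


def read_fractions(path) -> pd.DataFrame:
    return _read(path, "fraction_id", FRACTION_SCHEMA, "fraction metadata")


def read_samples(path) -> pd.DataFrame:
    return _read(path, "tube_id", SAMPLE_SCHEMA, "sample metadata")


def read_taxonomy(path) -> pd.DataFrame:
    df = _read(path, "taxon_id", ["taxon_id"], "taxonomy")
    return df.fillna("")


def read_calibration(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CALIBRATION_SCHEMA if c not in df.columns]
    if missing:
        raise SchemaError(f"calibration file {path} missing column(s): {missing}")
    return df


def load_inputs(features_path, fractions_path, samples_path, taxonomy_path):
    """Load and cross-validate the four input tables.

    Checks that every feature-table column has fraction metadata, every
    fraction's tube has sample metadata, and every taxon has taxonomy.
    Returns ``(features, fractions, samples, taxonomy, counts)``.
    """
    features = read_features(features_path)
    fractions = read_fractions(fractions_path)
    samples = read_samples(samples_path)
    taxonomy = read_taxonomy(taxonomy_path)

    orphan_cols = [c for c in features.columns if c not in fractions.index]
    if orphan_cols:
        raise SchemaError(
            f"feature-table column(s) without fraction metadata: {orphan_cols[:5]}"
        )
    orphan_fracs = [f for f in fractions.index if f not in set(features.columns)]
    if orphan_fracs:
        raise SchemaError(
            f"fraction(s) without feature-table column: {orphan_fracs[:5]}"
        )
    orphan_tubes = sorted(set(fractions["tube_id"]) - set(samples.index))
    if orphan_tubes:
        raise SchemaError(f"tube(s) without sample metadata: {orphan_tubes[:5]}")
    missing_tax = [t for t in features.index if t not in taxonomy.index]
    if missing_tax:
        raise SchemaError(f"taxa without taxonomy: {missing_tax[:5]}")

    counts = {
        "n_taxa": int(features.shape[0]),
        "n_fractions": int(fractions.shape[0]),
        "n_tubes": int(samples.shape[0]),
        "n_treatments": int(samples["treatment"].nunique()),
        "total_reads": float(features.to_numpy().sum()),
    }
    return features, fractions, samples, taxonomy, counts


def write_tsv(df: pd.DataFrame, path, index_label=None) -> None:
    """Write a table as UTF-8 TSV with '.' decimals (the canonical format)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)


def write_experiment(sim: SimulatedExperiment, out_dir) -> dict:
    """Write a simulated experiment as the four input TSVs + ground_truth.json.

    Returns the mapping of logical names to file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": out / "features.tsv",
        "fractions": out / "fractions.tsv",
        "samples": out / "samples.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_tsv(sim.features, paths["features"], index_label="taxon_id")
    write_tsv(sim.fractions, paths["fractions"], index_label="fraction_id")
    write_tsv(sim.samples, paths["samples"], index_label="tube_id")
    write_tsv(sim.taxonomy, paths["taxonomy"], index_label="taxon_id")
    truth = {
        "taxa": sim.truth.taxa.to_dict(orient="list"),
        "treatment_growing_share": sim.truth.treatment_growing_share.to_dict(),
        "soil_water_ape": sim.truth.soil_water_ape.to_dict(),
        "abundances": sim.truth.abundances.to_dict(),
        "incubation_days": sim.truth.incubation_days,
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=1, default=lambda o: bool(o) if isinstance(o, np.bool_) else o)
    return {k: str(v) for k, v in paths.items()}
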