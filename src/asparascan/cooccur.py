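"""Per-species asparaginase repertoires and short/long co-occurrence statistics.

For every bacterial species the long-chain (class 1) enzymes are tallied by
predicted localization (cytoplasmic, SPI-secreted, SPII-lipid-anchored) and
short-chain enzymes are counted; species are then grouped by their long-chain
count (0, 1, >1) and the fraction of each group carrying at least one
short-chain enzyme is reported.

Species with multiple sequenced genomes are collapsed presence-based by
default: identical (length class, localization, protein sequence) entries
across a species' genomes count once.  A per-genome mode treats each genome
as the counting unit instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "tally_repertoires",
    "repertoire_histogram",
    "sc_fraction_by_lc_count",
    "LC_GROUPS",
]

LC_GROUPS = ("0", "1", ">1")

_REQUIRED = {"species", "length_class", "localization"}


def tally_repertoires(
    records: pd.DataFrame,
    roster=None,
    collapse: str = "species",
) -> pd.DataFrame:
    """One repertoire row per species: long-chain counts by localization plus
    the short-chain count.

    ``roster`` (iterable of species names) forces all-zero rows for species
    without records.  ``collapse='species'`` deduplicates identical proteins
    across a species' genomes; ``collapse='genome'`` counts every genome's
    records.
    """
    missing = _REQUIRED - set(records.columns)
    if missing:
        raise ValueError(f"records missing required column(s): {sorted(missing)}")
    if collapse not in ("species", "genome"):
        raise ValueError("collapse must be 'species' or 'genome'")
    df = records
    if collapse == "species" and len(df):
        subset = ["species", "length_class", "localization"]
        if "protein" in df.columns:
            subset.append("protein")
        df = df.drop_duplicates(subset=subset)

    species_list = sorted(set(df["species"]) | set(roster or []))
    rows = []
    for sp in species_list:
        sub = df[df["species"] == sp]
        lc = sub[sub["length_class"] == "long"]
        rows.append({
            "species": sp,
            "n_lc_cytoplasmic": int((lc["localization"] == "cytoplasmic").sum()),
            "n_lc_SPI": int((lc["localization"] == "SPI").sum()),
            "n_lc_SPII": int((lc["localization"] == "SPII").sum()),
            "n_sc": int((sub["length_class"] == "short").sum()),
        })
    out = pd.DataFrame(rows, columns=[
        "species", "n_lc_cytoplasmic", "n_lc_SPI", "n_lc_SPII", "n_sc"])
    out["n_lc"] = out[["n_lc_cytoplasmic", "n_lc_SPI", "n_lc_SPII"]].sum(axis=1)
    return out


def repertoire_histogram(repertoires: pd.DataFrame) -> pd.DataFrame:
    """Species counts per (n_cyt, n_SPI, n_SPII) long-chain combination,
    ordered by decreasing count."""
    counts = (
        repertoires
        .groupby(["n_lc_cytoplasmic", "n_lc_SPI", "n_lc_SPII"])
        .size()
        .reset_index(name="n_species")
        .sort_values(
            ["n_species", "n_lc_cytoplasmic", "n_lc_SPI", "n_lc_SPII"],
            ascending=[False, True, True, True],
        )
        .reset_index(drop=True)
    )
    return counts


def sc_fraction_by_lc_count(repertoires: pd.DataFrame) -> pd.DataFrame:
    """Fraction of species carrying >= 1 short-chain enzyme, by long-chain
    count group {0, 1, >1}.

    An empty group is reported with fraction NaN (undefined), never 0.
    """
    lc = repertoires["n_lc"]
    groups = {
        "0": repertoires[lc == 0],
        "1": repertoires[lc == 1],
        ">1": repertoires[lc > 1],
    }
    rows = []
    for name in LC_GROUPS:
        sub = groups[name]
        n = len(sub)
        n_sc = int((sub["n_sc"] >= 1).sum())
        rows.append({
            "lc_group": name,
            "n_species": n,
            "n_with_sc": n_sc,
            "fraction": (n_sc / n) if n else np.nan,
            "undefined": n == 0,
        })
    return pd.DataFrame(rows)
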