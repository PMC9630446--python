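"""Covariate assembly: physico-chemical deltas, BLOSUM62, conservation, ingestion.

The modeling table carries 14 covariates per variant: six mutant-minus-wildtype
side-chain property deltas, the BLOSUM62 substitution score, the ingested
unfolding ΔΔG and the three Mutation-Assessor-style phylogenetic scores
(functional impact / family conservation / clade specificity), and the three
mutation-proximity scores.  ΔΔG and the phylogenetic scores come from external
predictors and are never computed here.

Conservation for the family-vs-clade comparison is the normalized
Shannon-entropy complement of an alignment column, with the gap character as a
21st symbol.
"""

from __future__ import annotations

import math
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .variant_io import AA_ALPHABET, CoordinateMap, ParalogAlignment, VariantTable

DELTA_PROPERTIES = {
    "datoms": "atoms",
    "dhdonors": "hdonors",
    "dhacceptors": "hacceptors",
    "dcharge": "charge",
    "dhydro": "kd_hydro",
    "dvolume": "volume",
}

#: the 14 modeling covariates, in reporting order
MODELING_COVARIATES = [
    "datoms", "dhdonors", "dhacceptors", "dcharge", "dhydro", "dvolume",
    "blosum62", "ddg", "fi_score", "vc_score", "vs_score",
    "prox_ratio_each", "prox_ratio_all", "pclust_score",
]

#: covariates ingested from external predictors (never computed locally)
INGESTED_COVARIATES = ["ddg", "fi_score", "vc_score", "vs_score"]


@lru_cache(maxsize=1)
def aa_property_table() -> pd.DataFrame:
    path = resources.files("vusannot.data") / "aa_properties.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#", index_col="aa")
    return df


def _check_aa(*residues: str) -> None:
    for aa in residues:
        if aa not in AA_ALPHABET:
            raise ValueError(f"nonstandard residue {aa!r}")


def physchem_deltas(wt_aa: str, mut_aa: str) -> dict[str, float]:
    """Mutant-minus-wildtype side-chain property differences."""
    _check_aa(wt_aa, mut_aa)
    props = aa_property_table()
    return {name: float(props.loc[mut_aa, col] - props.loc[wt_aa, col])
            for name, col in DELTA_PROPERTIES.items()}


@lru_cache(maxsize=1)
def _blosum62():
    return substitution_matrices.load("BLOSUM62")


def blosum62(wt_aa: str, mut_aa: str) -> int:
    """Canonical BLOSUM62 log-odds score (half-bits)."""
    _check_aa(wt_aa, mut_aa)
    return int(_blosum62()[wt_aa, mut_aa])


def conservation_score(aln: ParalogAlignment, column: int,
                       subset: list[str] | None = None) -> float:
    """1 - H/Hmax over a column's residues; gaps count as a 21st symbol.

    Hmax = log(min(n, 21)) so a fully diverse column scores 0 and a
    monomorphic column scores 1.  A single-sequence subset scores 1 by
    convention.
    """
    members = subset if subset is not None else aln.members
    if not members:
        raise ValueError("subset must be non-empty")
    symbols = [aln.sequences[m][column - 1] for m in members]
    n = len(symbols)
    if n == 1:
        return 1.0
    _, counts = np.unique(symbols, return_counts=True)
    p = counts / n
    h = float(-(p * np.log(p)).sum())
    hmax = math.log(min(n, 21))
    return 1.0 - h / hmax


def family_vs_clade(aln: ParalogAlignment, table: VariantTable,
                    cmap: CoordinateMap) -> pd.DataFrame:
    """Per-variant family and clade conservation of the mutated column."""
    if not aln.clades or any(m not in aln.clades for m in aln.members):
        missing = [m for m in aln.members if m not in (aln.clades or {})]
        raise ValueError(f"members without a clade label: {missing}")
    fam, cla, cols = [], [], []
    for row in table.df.itertuples(index=False):
        col = cmap.column_from_full(str(row.protein_id), int(row.position))
        clade = aln.clades[str(row.protein_id)]
        clade_members = [m for m in aln.members if aln.clades[m] == clade]
        cols.append(col)
        fam.append(conservation_score(aln, col))
        cla.append(conservation_score(aln, col, clade_members))
    return pd.DataFrame({"column": cols, "family_score": fam,
                         "clade_score": cla}, index=table.df.index)


def assemble_features(table: VariantTable, cluster_scores: pd.DataFrame,
                      conservation: pd.DataFrame | None = None) -> pd.DataFrame:
    """One modeling row per variant: key, computed deltas, ingested scores, cluster scores.

    Physico-chemical deltas and BLOSUM62 are (re)computed from the residue
    pair; ingested covariates are taken from the table's attachments and
    flagged per row in ``n_missing`` when absent.
    """
    df = table.df
    if not cluster_scores.index.equals(df.index):
        raise ValueError("cluster scores are not aligned with the variant table")
    out = df[["protein_id", "position", "wt_aa", "mut_aa"]].copy()
    deltas = [physchem_deltas(r.wt_aa, r.mut_aa) for r in df.itertuples(index=False)]
    for name in DELTA_PROPERTIES:
        out[name] = [d[name] for d in deltas]
    out["blosum62"] = [blosum62(r.wt_aa, r.mut_aa) for r in df.itertuples(index=False)]
    for name in INGESTED_COVARIATES:
        out[name] = pd.to_numeric(df[name], errors="coerce") \
            if name in df.columns else np.nan
    for name in ["prox_ratio_each", "prox_ratio_all", "pclust_score"]:
        out[name] = cluster_scores[name]
    if conservation is not None:
        out["family_cons"] = conservation["family_score"]
        out["clade_cons"] = conservation["clade_score"]
    out["n_missing"] = out[MODELING_COVARIATES].isna().sum(axis=1)
    return out
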