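"""Synthetic benchmark generator emulating a paralog-family variant screen.

Produces a complete stand-in study: a six-member family alignment (three
clades of two members, mirroring a methyltransferase family whose clades
diverged in product specificity), cancer-associated missense variants on
three of the members (29/44/26 by default), plate-assay-style activities on
two substrate channels, and external-predictor score columns with configurable
discriminative power.  Ground truth (planted labels, hotspot membership, the
planted predictive hierarchy) is retained for parameter-recovery tests.

The planted structure mirrors the study conditions: 62/35/3% LOF/neutral/GOF;
loss-of-function variants preferentially fall inside five sequence hotspots
while neutral variants scatter uniformly; functional-impact scores are drawn
conditionally on the planted label with realistic overlap.  A separate
:func:`planted_hierarchy_dataset` provides a two-level decision structure
(conservation first, clustering second) for topology-recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from .activity import GOF, LOF, NEUTRAL
from .variant_io import (AA_ALPHABET, ParalogAlignment, VariantTable,
                         write_alignment_fasta, write_variant_table)

DEFAULT_SEED = 20221102

FAMILY_MEMBERS = ("MLL1", "MLL2", "MLL3", "MLL4", "SETD1A", "SETD1B")
FAMILY_CLADES = {"MLL1": "clade1", "MLL2": "clade1",
                 "MLL3": "clade2", "MLL4": "clade2",
                 "SETD1A": "clade3", "SETD1B": "clade3"}
# full-length residue number of the first construct residue, per member
FAMILY_OFFSETS = {"MLL1": 3710, "MLL2": 5278, "MLL3": 4652,
                  "MLL4": 5246, "SETD1A": 1441, "SETD1B": 1631}


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic variant screen."""

    construct_length: int = 260
    mutated_members: tuple[str, ...] = ("MLL1", "MLL2", "MLL3")
    n_variants: tuple[int, ...] = (29, 44, 26)
    # five hotspots echoing the structural clusters; width in residues
    hotspot_centers: tuple[int, ...] = (30, 85, 140, 195, 245)
    hotspot_width: int = 9
    label_proportions: dict = field(default_factory=lambda: {
        LOF: 0.62, NEUTRAL: 0.35, GOF: 0.03})
    lof_hotspot_enrichment: float = 0.8   # P(a LOF variant is placed in a hotspot)
    # activity model: truncated-at-0 normals per label (primary channel me0)
    lof_activity: tuple[float, float] = (0.15, 0.10)
    neutral_activity: tuple[float, float] = (1.00, 0.15)
    gof_activity: tuple[float, float] = (1.80, 0.30)  # on the gained channel
    gof_switch_fraction: float = 0.5
    replicate_sd: float = 0.05
    n_replicates: int = 2
    # phylogenetic predictor scores, conditional on the planted label
    fi_lof: tuple[float, float] = (3.5, 0.6)
    fi_neutral: tuple[float, float] = (1.5, 0.8)
    # external predictor call rates: (sensitivity for LOF, specificity for not-LOF)
    program_rates: dict = field(default_factory=lambda: {
        "fathmm": (0.06, 0.97), "polyphen2": (0.86, 0.10), "opai": (0.64, 0.62)})
    # P(a PolyPhen-2 false positive sits at a clade-specific conserved column):
    # FP positions are ortholog-conserved but paralog-divergent
    fp_clade_site_prob: float = 0.7
    ddg_lof: tuple[float, float] = (1.8, 1.2)
    ddg_neutral: tuple[float, float] = (0.4, 0.8)
    # alignment evolution
    clade_substitution_rate: float = 0.10
    member_substitution_rate: float = 0.05
    clade_specific_site_frac: float = 0.10
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if abs(sum(self.label_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("label proportions must sum to 1")
        hw = self.hotspot_width // 2
        for c in self.hotspot_centers:
            if not 1 + hw <= c <= self.construct_length - hw:
                raise ValueError(f"hotspot at {c} does not fit in the construct")
        if len(self.mutated_members) != len(self.n_variants):
            raise ValueError("one variant count per mutated member")

    @property
    def n_total(self) -> int:
        return sum(self.n_variants)


def default_config() -> SimConfig:
    return SimConfig()


@dataclass
class SimBundle:
    """Everything a pipeline run needs plus the ground truth behind it."""

    config: SimConfig
    alignment: ParalogAlignment
    offsets: dict[str, int]
    table: VariantTable
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_variant_table(self.table, outdir / "variants.tsv")
        write_alignment_fasta(self.alignment, outdir / "alignment.fasta")
        members = {pid: {"clade": self.alignment.clades[pid],
                         "offset": int(self.offsets[pid])}
                   for pid in self.alignment.members}
        (outdir / "members.yaml").write_text(
            yaml.safe_dump(members, sort_keys=True))
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True))
        manifest = {"config": dataclasses.asdict(self.config),
                    "seed": self.config.seed}
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=list))


def _label_counts(props: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n variants to labels."""
    raw = {k: v * n for k, v in props.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    rem = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:rem]:
        counts[k] += 1
    return counts


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  size: int | None = None) -> np.ndarray | float:
    """Normal draw truncated below at 0 by resampling."""
    x = rng.normal(mean, sd, size)
    for _ in range(100):
        neg = x < 0
        if not np.any(neg):
            break
        x = np.where(neg, rng.normal(mean, sd, size), x)
    return np.clip(x, 0.0, None)


def _evolve_family(cfg: SimConfig, rng: np.random.Generator,
                   extra_special: set[int] = frozenset()) -> ParalogAlignment:
    """Ancestor -> clade -> member substitution model over the construct.

    ``extra_special`` columns (0-based) are forced clade-specific on top of
    the randomly chosen fraction: conserved within every clade yet divergent
    between clades.
    """
    L = cfg.construct_length
    alphabet = np.array(list(AA_ALPHABET))
    ancestor = rng.choice(alphabet, size=L)
    n_special = int(round(cfg.clade_specific_site_frac * L))
    special = np.array(sorted(set(rng.choice(L, size=n_special, replace=False))
                              | set(extra_special)), dtype=int)
    clade_names = sorted(set(FAMILY_CLADES.values()))
    # clade-specific columns: conserved within a clade, divergent across clades
    special_residues = {}
    for col in special:
        picks = rng.choice(alphabet, size=len(clade_names), replace=False)
        special_residues[col] = dict(zip(clade_names, picks))
    clade_seqs = {}
    for clade in clade_names:
        seq = ancestor.copy()
        sub = rng.random(L) < cfg.clade_substitution_rate
        seq[sub] = rng.choice(alphabet, size=int(sub.sum()))
        for col in special:
            seq[col] = special_residues[col][clade]
        clade_seqs[clade] = seq
    sequences = {}
    for pid in FAMILY_MEMBERS:
        seq = clade_seqs[FAMILY_CLADES[pid]].copy()
        sub = rng.random(L) < cfg.member_substitution_rate
        sub[special] = False  # clade-diagnostic sites stay clade-conserved
        seq[sub] = rng.choice(alphabet, size=int(sub.sum()))
        sequences[pid] = "".join(seq)
    aln = ParalogAlignment(sequences, dict(FAMILY_CLADES))
    aln.special_columns = sorted(int(c) + 1 for c in special)  # 1-based, for truth
    return aln


def _hotspot_columns(cfg: SimConfig) -> list[np.ndarray]:
    hw = cfg.hotspot_width // 2
    return [np.arange(c - hw, c + hw + 1) for c in cfg.hotspot_centers]


def generate(config: SimConfig | None = None) -> SimBundle:
    """Deterministically (per seed) generate a full synthetic study bundle."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    hotspots = _hotspot_columns(cfg)
    hotspot_set = set(int(c) for h in hotspots for c in h)
    n = cfg.n_total
    # worst case every LOF variant of the largest member lands in a hotspot
    lof_demand = int(np.ceil(max(cfg.n_variants) * cfg.label_proportions[LOF]))
    if len(hotspot_set) < lof_demand:
        raise ValueError("hotspots too small to host the requested variants")

    # labels: exact apportioned counts, shuffled, then sliced per member
    counts = _label_counts(cfg.label_proportions, n)
    labels = np.array([lab for lab, c in counts.items() for _ in range(c)])
    rng.shuffle(labels)
    # predictor call indicators drawn up front: the columns where PolyPhen-2
    # false positives land will be made clade-specific during evolution
    is_lof_planted = labels == LOF
    called = {}
    for prog, (sens, spec) in cfg.program_rates.items():
        u = rng.random(n)
        called[prog] = np.where(is_lof_planted, u < sens, u > spec)

    # place variants on the column grid: LOF enriched in hotspots, rest uniform
    rows = []
    i = 0
    for pid, n_member in zip(cfg.mutated_members, cfg.n_variants):
        used: set[int] = set()
        for _ in range(n_member):
            lab = labels[i]
            in_hotspot = lab == LOF and rng.random() < cfg.lof_hotspot_enrichment
            for _attempt in range(10_000):
                if in_hotspot:
                    h = hotspots[int(rng.integers(len(hotspots)))]
                    col = int(h[int(rng.integers(len(h)))])
                else:
                    col = int(rng.integers(1, cfg.construct_length + 1))
                if col not in used:
                    break
            else:
                raise ValueError("could not place variant; hotspots too crowded")
            used.add(col)
            rows.append({"protein_id": pid,
                         "position": FAMILY_OFFSETS[pid] + col - 1,
                         "column": col, "label": lab,
                         "in_hotspot": col in hotspot_set})
            i += 1
    df = pd.DataFrame(rows)

    # evolve the family afterwards so false-positive columns (called damaging,
    # functionally neutral) can be forced clade-specific: ortholog-conserved
    # within clades yet divergent between clades
    fp_cols = {int(c) - 1 for c, lab, cal in
               zip(df["column"], df["label"], called["polyphen2"])
               if lab != LOF and cal and rng.random() < cfg.fp_clade_site_prob}
    aln = _evolve_family(cfg, rng, extra_special=fp_cols)

    wt_list, mut_list = [], []
    for row in df.itertuples(index=False):
        wt = aln.ungapped(row.protein_id)[row.column - 1]
        mut = wt
        while mut == wt:
            mut = AA_ALPHABET[int(rng.integers(20))]
        wt_list.append(wt)
        mut_list.append(mut)
    df.insert(2, "wt_aa", wt_list)
    df.insert(3, "mut_aa", mut_list)

    # activities: label-conditional true means, then replicate noise per channel
    gof_mode_truth = []
    me0_true = np.empty(n)
    me1_true = np.empty(n)
    for j, lab in enumerate(df["label"]):
        if lab == LOF:
            me0_true[j] = _trunc_normal(rng, *cfg.lof_activity)
            me1_true[j] = _trunc_normal(rng, *cfg.lof_activity)
            gof_mode_truth.append(None)
        elif lab == NEUTRAL:
            me0_true[j] = _trunc_normal(rng, *cfg.neutral_activity)
            me1_true[j] = _trunc_normal(rng, *cfg.neutral_activity)
            gof_mode_truth.append(None)
        else:  # GOF is realized on the me1 channel: plain gain keeps normal
            # monomethylation; switch variants lose me0 while gaining me1
            if rng.random() < cfg.gof_switch_fraction:
                me0_true[j] = _trunc_normal(rng, *cfg.lof_activity)
                gof_mode_truth.append("switch")
            else:
                me0_true[j] = _trunc_normal(rng, *cfg.neutral_activity)
                gof_mode_truth.append("gain")
            me1_true[j] = _trunc_normal(rng, *cfg.gof_activity)
    reps0 = np.clip(me0_true[:, None]
                    + rng.normal(0, cfg.replicate_sd, (n, cfg.n_replicates)),
                    0, None)
    reps1 = np.clip(me1_true[:, None]
                    + rng.normal(0, cfg.replicate_sd, (n, cfg.n_replicates)),
                    0, None)
    df["activity_me0"] = reps0.mean(axis=1)
    df["activity_me1"] = reps1.mean(axis=1)
    df["activity_sd"] = reps0.std(axis=1, ddof=1) if cfg.n_replicates > 1 else 0.0

    # phylogenetic scores: label-conditional with realistic overlap
    is_lof = (df["label"] == LOF).to_numpy()
    fi = np.where(is_lof,
                  rng.normal(*cfg.fi_lof, n), rng.normal(*cfg.fi_neutral, n))
    df["fi_score"] = np.round(fi, 3)
    df["vc_score"] = np.round(0.8 * fi + rng.normal(0, 0.3, n), 3)
    df["vs_score"] = np.round(0.6 * fi + rng.normal(0, 0.4, n), 3)

    # external predictor scores: draw in the called / not-called score region
    df["fathmm"] = np.round(np.where(called["fathmm"],
                                     rng.uniform(-3.0, -0.76, n),
                                     rng.uniform(-0.74, 2.0, n)), 3)
    df["polyphen2"] = np.round(np.where(called["polyphen2"],
                                        rng.uniform(0.801, 1.0, n),
                                        rng.uniform(0.0, 0.799, n)), 3)
    df["opai"] = np.round(np.where(called["opai"],
                                   rng.uniform(0.95, 1.0, n),
                                   rng.uniform(0.20, 0.949, n)), 3)
    df["ddg"] = np.round(np.where(is_lof, rng.normal(*cfg.ddg_lof, n),
                                  rng.normal(*cfg.ddg_neutral, n)), 3)

    # physico-chemical deltas and BLOSUM62 from the actual residue pair
    deltas = [feat.physchem_deltas(w, m) for w, m in zip(df["wt_aa"], df["mut_aa"])]
    for name in feat.DELTA_PROPERTIES:
        df[name] = [d[name] for d in deltas]
    df["blosum62"] = [feat.blosum62(w, m) for w, m in zip(df["wt_aa"], df["mut_aa"])]

    truth = {
        "labels": df["label"].tolist(),
        "gof_mode": gof_mode_truth,
        "in_hotspot": df["in_hotspot"].tolist(),
        "hotspot_columns": sorted(hotspot_set),
        "clade_specific_columns": aln.special_columns,
        "label_counts": counts,
        "dominant_covariate": "fi_score",
        "seed": cfg.seed,
    }
    table = VariantTable(df.drop(columns=["column", "label", "in_hotspot"]))
    return SimBundle(cfg, aln, dict(FAMILY_OFFSETS), table, truth)


def planted_step_dataset(n: int = 100, n_covariates: int = 5,
                         theta: float = 5.0, gap: float = 0.5,
                         low: float = 0.1, high: float = 1.0,
                         noise_sd: float = 0.05,
                         seed: int = DEFAULT_SEED) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Step-response fixture: activity steps at ``theta`` in the first covariate.

    The dominant covariate has an empty gap of width ``gap`` above ``theta``
    so split-recovery can be checked against the planted interval; the other
    covariates are pure noise.  Returns (features, activity, truth).
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.uniform(0, 10, size=(n, n_covariates)),
                     columns=[f"x{j + 1}" for j in range(n_covariates)])
    x = X["x1"].to_numpy()
    x = np.where(x >= theta, x + gap, x)  # carve the gap (theta, theta + gap)
    X["x1"] = x
    y = np.where(x < theta, high, low) + rng.normal(0, noise_sd, n)
    truth = {"covariate": "x1", "gap_low": theta, "gap_high": theta + gap,
             "low": low, "high": high}
    return X, y, truth


def planted_hierarchy_dataset(n: int = 100, theta_fi: float = 3.0,
                              theta_pclust: float = 9.0, noise_sd: float = 0.05,
                              high_fi_frac: float = 0.6,
                              seed: int = DEFAULT_SEED) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Two-level fixture: conservation decides first, clustering second.

    High functional-impact score (> ``theta_fi``) implies loss of function
    outright; among low-impact variants, those with a high cluster score
    (> ``theta_pclust``) are also loss of function — the configuration in
    which clustering carries information that conservation misses.  Noise
    covariates make covariate selection non-trivial.
    """
    rng = np.random.default_rng(seed)
    n_hi = int(n * high_fi_frac)
    fi = np.concatenate([rng.uniform(theta_fi + 0.3, theta_fi + 2.0, n_hi),
                         rng.uniform(0.0, theta_fi - 0.3, n - n_hi)])
    pclust = rng.uniform(0.0, 12.0, n)
    pclust = np.where(np.abs(pclust - theta_pclust) < 0.3,
                      pclust + 0.6, pclust)  # keep the split bracketed
    lof = (fi > theta_fi) | (pclust > theta_pclust)
    y = np.where(lof, 0.1, 1.0) + rng.normal(0, noise_sd, n)
    X = pd.DataFrame({"fi_score": fi, "pclust_score": pclust,
                      "datoms": rng.normal(0, 2, n),
                      "blosum62": rng.integers(-4, 4, n).astype(float),
                      "ddg": rng.normal(0.5, 1.0, n)})
    perm = rng.permutation(n)
    truth = {"root": "fi_score", "second": "pclust_score",
             "theta_fi": theta_fi, "theta_pclust": theta_pclust}
    return X.iloc[perm].reset_index(drop=True), y[perm], truth
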