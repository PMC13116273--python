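"""Synthetic annotated mitogenomes with recorded ground truth.

The generator emulates the statistical structure of velvet-worm (and, more
broadly, panarthropod) mitogenomes so that every analysis stage can be tested
against known truth: ~14.4-14.9 kb circular genomes at ~77% A+T, the full
13 PCG + 2 rRNA + 22 tRNA complement minus configured losses, a configurable
GC-skew regime (globally positive / globally negative / bimodal), gene orders
derived from an ancestral arthropod-like template by random signed
inversions, and per-group synonymous codon-bias profiles.

Skew is imposed through region-wise base-sampling probabilities rather than
post-hoc edits, so reading frames stay intact: intergenic and RNA spans are
drawn base-by-base with the regime's G:C imbalance, and coding spans are
drawn codon-by-codon from the bias profile with its synonymous and
amino-acid choices tilted toward the same imbalance (the tilt is calibrated
so the expected coding-strand skew matches the regime amplitude). Realized
skews are therefore stochastic and verified within tolerance, not exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd

from .composition import GLOBALLY_POSITIVE, GLOBALLY_NEGATIVE, BIMODAL
from .codon_usage import INVERTEBRATE_MITO
from .genome_io import (AnnotatedMitogenome, GeneFeature, PCG, TRNAS,
                        revcomp, write_genbank)
from .gene_order import SignedGeneOrder

REGIMES = (GLOBALLY_POSITIVE, GLOBALLY_NEGATIVE, BIMODAL)

_SENSE = INVERTEBRATE_MITO.sense_codons
_N_AT = np.array([c.count("A") + c.count("T") for c in _SENSE], dtype=float)
_N_GC_DIFF = np.array([c.count("G") - c.count("C") for c in _SENSE],
                      dtype=float)
_N_GC_SUM = np.array([c.count("G") + c.count("C") for c in _SENSE],
                     dtype=float)


# ancestral template ----------------------------------------------------------


def _template_table() -> pd.DataFrame:
    ref = resources.files("mitoremodel").joinpath("data/ancestral_order.tsv")
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    required = {"position", "label", "cls", "sign", "length"}
    if not required.issubset(df.columns) or df.empty:
        raise ValueError("ancestral template fixture is missing or corrupt")
    return df.sort_values("position")


def ancestral_template() -> tuple[SignedGeneOrder, dict[str, int]]:
    """The bundled ancestral arthropod-like arrangement (37 genes) and its
    per-gene template lengths."""
    df = _template_table()
    genes = tuple((str(r.label), int(r.sign)) for r in df.itertuples())
    lengths = {str(r.label): int(r.length) for r in df.itertuples()}
    order = SignedGeneOrder("ancestral_template", genes, "circular")
    return order, lengths


def _template_parts():
    order, lengths = ancestral_template()
    classes = {str(r.label): str(r.cls) for r in _template_table().itertuples()}
    return order, lengths, classes


# codon-bias profiles ---------------------------------------------------------

PROFILE_IDS = ("balanced", "A3", "U3")


def _at_fraction(weights: np.ndarray) -> float:
    w = weights / weights.sum()
    return float(np.dot(w, _N_AT) / 3.0)


def default_codon_profile(profile_id: str = "balanced",
                          at_content: float = 0.77) -> np.ndarray:
    """Codon weights over the 62 sense codons of table 5.

    All profiles are A/T-rich (calibrated so the expected CDS A+T fraction
    matches ``at_content``) and prefer A/U-ending codons, mirroring the
    third-position A/U bias seen across panarthropod mitogenomes. ``A3``
    and ``U3`` shift that third-position preference toward A- and U-ending
    codons respectively — two distinguishable group profiles for
    planted-structure tests.
    """
    if profile_id not in PROFILE_IDS:
        raise ValueError(f"unknown codon profile {profile_id!r}")
    pref_a, pref_u = {"balanced": (2.0, 2.0),
                      "A3": (3.5, 1.2),
                      "U3": (1.2, 3.5)}[profile_id]
    third = np.array([pref_a if c[2] == "A" else pref_u if c[2] == "T"
                      else 1.0 for c in _SENSE])

    def weights(r: float) -> np.ndarray:
        return np.power(r, _N_AT) * third

    lo, hi = 0.2, 50.0
    for _ in range(80):  # bisection on the AT-richness knob
        mid = 0.5 * (lo + hi)
        if _at_fraction(weights(mid)) < at_content:
            lo = mid
        else:
            hi = mid
    return weights(0.5 * (lo + hi))


def tilt_profile(weights: np.ndarray,
                 skew_target: float) -> tuple[np.ndarray, float]:
    """Tilt codon weights toward a target coding-strand GC skew.

    Weights are multiplied by ``exp(t * (nG - nC))`` with t found by
    bisection so the expected (G - C)/(G + C) over sampled codons equals the
    target; returns the tilted weights and the achieved expected skew (which
    may fall short of an unreachable target).
    """

    def skew(t: float) -> float:
        q = weights * np.exp(t * _N_GC_DIFF)
        q /= q.sum()
        return float(np.dot(q, _N_GC_DIFF) / np.dot(q, _N_GC_SUM))

    lo, hi = -4.0, 4.0
    if skew_target <= skew(lo):
        t = lo
    elif skew_target >= skew(hi):
        t = hi
    else:
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if skew(mid) < skew_target:
                lo = mid
            else:
                hi = mid
        t = 0.5 * (lo + hi)
    tilted = weights * np.exp(t * _N_GC_DIFF)
    return tilted / tilted.sum(), skew(t)


# configuration and truth ------------------------------------------------------


@dataclass
class SynthConfig:
    """Study conditions for one batch of synthetic genomes."""

    seed: int
    n_genomes: int = 8
    at_content: float = 0.77
    regime: str = BIMODAL
    amplitude: float = 0.15
    n_inversions: int = 0
    trna_losses: tuple = ()
    codon_profile: str = "balanced"
    length_range: tuple = (14_400, 14_900)

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        bad = [t for t in self.trna_losses if t not in TRNAS]
        if bad:
            raise ValueError(f"non-canonical tRNA losses: {bad}")
        if not (0 < self.at_content < 1):
            raise ValueError("at_content must be in (0, 1)")
        if not (0 <= self.amplitude < 1):
            raise ValueError("amplitude must be in [0, 1)")


@dataclass
class SynthTruth:
    """Everything needed to re-derive the expected analysis outputs."""

    genome_id: str
    seed: int
    index: int
    regime: str
    amplitude: float
    inversions: list
    trna_losses: list
    codon_profile: str
    length: int
    at_content: float


# generation -------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _background(rng, n: int, at: float, skew: float) -> np.ndarray:
    gc = 1.0 - at
    p = np.array([at / 2, gc * (1 - skew) / 2, gc * (1 + skew) / 2, at / 2])
    return rng.choice(_BASES, size=n, p=p)


def _sample_cds(rng, n_codons: int, probs: np.ndarray) -> str:
    start = "ATG" if rng.random() < 0.5 else "ATA"
    body_idx = rng.choice(len(_SENSE), size=n_codons - 2, p=probs)
    return start + "".join(_SENSE[i] for i in body_idx) + "TAA"


def apply_inversions(order: SignedGeneOrder,
                     inversions) -> SignedGeneOrder:
    """Apply signed inversions given as (lo, hi) index pairs (inclusive)."""
    genes = list(order.genes)
    for lo, hi in inversions:
        seg = [(g, -s) for g, s in reversed(genes[lo : hi + 1])]
        genes[lo : hi + 1] = seg
    return SignedGeneOrder(order.genome_id, tuple(genes), order.topology,
                           order.classes_included)


def random_inversions(rng, n_genes: int, k: int) -> list:
    """k random segments in [1, n_genes); index 0 (the anchor) never moves."""
    out = []
    for _ in range(k):
        i, j = sorted(rng.integers(1, n_genes, size=2))
        out.append((int(i), int(j)))
    return out


def generate_genome(config: SynthConfig, genome_index: int,
                    genome_id: str | None = None,
                    inversions=None) -> tuple[AnnotatedMitogenome, SynthTruth]:
    """Generate one annotated genome; deterministic given (seed, index).

    ``inversions`` overrides random drawing — used when several genomes must
    share one derived arrangement.
    """
    rng = np.random.default_rng([config.seed, genome_index])
    gid = genome_id or f"SYN{genome_index:03d}"

    template, lengths, classes = _template_parts()
    if inversions is None:
        inversions = random_inversions(rng, len(template.genes),
                                       config.n_inversions)
    order = apply_inversions(template, inversions)
    losses = set(config.trna_losses)
    genes = [(g, s) for g, s in order.genes if g not in losses]

    # gene lengths within +-10% of template; PCGs snap to codon multiples
    placed = []  # (label, cls, start, end, strand)
    cur = 0
    for label, sign in genes:
        n0 = lengths[label]
        n = int(round(n0 * rng.uniform(0.9, 1.1)))
        if classes[label] == PCG:
            n = max(9, 3 * int(round(n / 3)))
        placed.append((label, classes[label], cur, cur + n, sign))
        cur += n + int(rng.integers(0, 7))  # short intergenic spacer
    cur += int(rng.integers(60, 181))  # control-region-like terminal spacer
    length = cur

    base_w = default_codon_profile(config.codon_profile, config.at_content)
    probs_pos, _ = tilt_profile(base_w, config.amplitude)
    probs_neg, _ = tilt_profile(base_w, -config.amplitude)

    def region_skew(mid: float) -> float:
        if config.regime == GLOBALLY_POSITIVE:
            return config.amplitude
        if config.regime == GLOBALLY_NEGATIVE:
            return -config.amplitude
        return config.amplitude if mid < length / 2 else -config.amplitude

    # background (intergenic + RNA genes), drawn half-by-half for bimodal
    seq = np.empty(length, dtype="S1")
    half = length // 2
    if config.regime == BIMODAL:
        seq[:half] = _background(rng, half, config.at_content,
                                 config.amplitude)
        seq[half:] = _background(rng, length - half, config.at_content,
                                 -config.amplitude)
    else:
        seq[:] = _background(rng, length, config.at_content,
                             region_skew(0.0))

    features = []
    for label, cls, start, end, sign in placed:
        if cls == PCG:
            s_major = region_skew((start + end) / 2)
            s_coding = s_major if sign == 1 else -s_major
            probs = probs_pos if s_coding >= 0 else probs_neg
            cds = _sample_cds(rng, (end - start) // 3, probs)
            if sign == -1:
                cds = revcomp(cds)
            seq[start:end] = np.frombuffer(cds.encode(), dtype="S1")
        features.append(GeneFeature(label, cls, start, end, sign))

    genome = AnnotatedMitogenome(gid, seq.tobytes().decode(), "circular",
                                 features).validate()
    truth = SynthTruth(
        genome_id=gid, seed=config.seed, index=genome_index,
        regime=config.regime, amplitude=config.amplitude,
        inversions=[list(iv) for iv in inversions],
        trna_losses=sorted(losses), codon_profile=config.codon_profile,
        length=length, at_content=config.at_content)
    return genome, truth


def generate_dataset(config: SynthConfig):
    """n_genomes independent draws under one configuration."""
    pairs = [generate_genome(config, i) for i in range(config.n_genomes)]
    return [g for g, _ in pairs], [t for _, t in pairs]


# two-family study design ------------------------------------------------------

# fixed tRNA losses of the derived family (leaves 14 of 22)
DERIVED_FAMILY_LOSSES = ("trnA", "trnC", "trnE", "trnH",
                         "trnI", "trnQ", "trnT", "trnY")


@dataclass
class TwoFamilyDataset:
    """A derived family (A), an ancestral-order family (B), and an outgroup."""

    genomes: list
    truths: list
    groups: dict
    tree_newick: str
    outgroup_id: str
    derived_inversions: list = field(default_factory=list)


def generate_two_family_dataset(seed: int, n_per_family: int = 4,
                                n_derived_inversions: int = 3,
                                at_content: float = 0.77,
                                amplitude: float = 0.15) -> TwoFamilyDataset:
    """Emulate a family-level mitogenomic split.

    Group A: one shared derived gene order (a fixed inversion set from the
    ancestral template), globally positive GC skew, reduced tRNA set (14).
    Group B: ancestral gene order, bimodal skew, 18-22 tRNAs. One outgroup
    genome keeps the ancestral order with a globally negative skew.
    """
    template, _, _ = _template_parts()
    rng = np.random.default_rng([seed, 555])
    derived = random_inversions(rng, len(template.genes),
                                n_derived_inversions)

    genomes, truths, groups = [], [], {}
    cfg_a = SynthConfig(seed=seed, regime=GLOBALLY_POSITIVE,
                        amplitude=amplitude, at_content=at_content,
                        trna_losses=DERIVED_FAMILY_LOSSES,
                        codon_profile="A3")
    for i in range(n_per_family):
        g, t = generate_genome(cfg_a, 100 + i, genome_id=f"A{i + 1}",
                               inversions=derived)
        genomes.append(g)
        truths.append(t)
        groups[g.id] = "familyA"

    trna_pool = list(TRNAS)
    for i in range(n_per_family):
        loss_rng = np.random.default_rng([seed, 556, i])
        k = int(loss_rng.integers(0, 5))
        losses = tuple(sorted(loss_rng.choice(trna_pool, size=k,
                                              replace=False))) if k else ()
        cfg_b = SynthConfig(seed=seed, regime=BIMODAL, amplitude=amplitude,
                            at_content=at_content, trna_losses=losses,
                            codon_profile="U3")
        g, t = generate_genome(cfg_b, 200 + i, genome_id=f"B{i + 1}",
                               inversions=[])
        genomes.append(g)
        truths.append(t)
        groups[g.id] = "familyB"

    cfg_out = SynthConfig(seed=seed, regime=GLOBALLY_NEGATIVE,
                          amplitude=amplitude, at_content=at_content,
                          codon_profile="balanced")
    og, ot = generate_genome(cfg_out, 300, genome_id="OUT", inversions=[])
    genomes.append(og)
    truths.append(ot)
    groups[og.id] = "outgroup"

    ingroup = ",".join(g.id for g in genomes if g.id != "OUT")
    tree = f"(OUT,({ingroup}));"
    return TwoFamilyDataset(genomes, truths, groups, tree, "OUT",
                            [list(iv) for iv in derived])


def write_dataset(dataset: TwoFamilyDataset, out_dir) -> None:
    """GenBank + groups TSV + newick + truth JSON under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genbank(dataset.genomes, out / "genomes.gb")
    pd.DataFrame(
        [{"genome_id": k, "group": v} for k, v in dataset.groups.items()]
    ).to_csv(out / "groups.tsv", sep="\t", index=False)
    (out / "tree.nwk").write_text(dataset.tree_newick + "\n")
    payload = {
        "outgroup_id": dataset.outgroup_id,
        "derived_inversions": dataset.derived_inversions,
        "genomes": [asdict(t) for t in dataset.truths],
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1))
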