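"""Relative synonymous codon usage (RSCU) under the invertebrate
mitochondrial genetic code, and PCA of species x codon RSCU matrices.

RSCU for codon j of an amino acid with synonymous family size n and family
count total X is ``x_j / (X / n)``: the observed count divided by the count
expected were all synonyms used equally. RSCU 1 means no bias; exclusive use
of one codon gives RSCU = family size. Within every observed family the RSCU
values sum to the family size (mean 1) by construction — that identity is
enforced as an invariant throughout the tests.

The single supported code is NCBI translation table 5 (invertebrate
mitochondrial: AGA/AGG -> Ser, ATA -> Met, TGA -> Trp; stops TAA/TAG),
giving 62 sense codons. Codons are handled in DNA spelling (TTT not UUU).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from sklearn.decomposition import PCA

from .genome_io import AnnotatedMitogenome, PCG, extract_cds, DegenerateCDSError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino acid map plus synonymous families for one NCBI table."""

    table_id: int
    forward: dict          # sense codon -> one-letter amino acid
    stops: frozenset
    families: dict         # amino acid -> tuple of synonymous codons

    @property
    def sense_codons(self) -> tuple:
        return tuple(sorted(self.forward, key=lambda c: (self.forward[c], c)))

    def family_size(self, codon: str) -> int:
        return len(self.families[self.forward[codon]])


def genetic_code(table_id: int = 5) -> GeneticCode:
    """Build a :class:`GeneticCode`; table 5 is the code used throughout."""
    t = CodonTable.unambiguous_dna_by_id[table_id]
    forward = dict(t.forward_table)
    families: dict[str, list] = {}
    for codon, aa in forward.items():
        families.setdefault(aa, []).append(codon)
    return GeneticCode(
        table_id=table_id,
        forward=forward,
        stops=frozenset(t.stop_codons),
        families={aa: tuple(sorted(cs)) for aa, cs in families.items()},
    )


INVERTEBRATE_MITO = genetic_code(5)


@dataclass
class CodonCounts:
    """Pooled codon tallies for one genome: sense codons kept for RSCU,
    stops and ambiguous codons reported separately."""

    sense: Counter
    stops: Counter
    ambiguous: int = 0


def codon_counts(cds_set, code: GeneticCode = INVERTEBRATE_MITO) -> CodonCounts:
    """Pool codon counts over a genome's coding sequences.

    Each CDS must be a multiple of 3 (``extract_cds`` guarantees this). Stop
    codons and codons containing non-ACGT characters are excluded from the
    RSCU input but tallied for reporting.
    """
    cds_list = list(cds_set)
    if not cds_list:
        raise ValueError("empty CDS set")
    sense: Counter = Counter()
    stops: Counter = Counter()
    ambiguous = 0
    for cds in cds_list:
        if len(cds) % 3:
            raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
        s = cds.upper()
        for i in range(0, len(s), 3):
            codon = s[i : i + 3]
            if codon in code.forward:
                sense[codon] += 1
            elif codon in code.stops:
                stops[codon] += 1
            else:
                ambiguous += 1
    return CodonCounts(sense, stops, ambiguous)


def rscu(counts, code: GeneticCode = INVERTEBRATE_MITO) -> dict:
    """RSCU per sense codon; codons of unobserved amino acids are NaN
    (missing), not zero."""
    sense = counts.sense if isinstance(counts, CodonCounts) else counts
    for codon, x in sense.items():
        if x < 0:
            raise ValueError(f"negative count for {codon}")
        if codon not in code.forward:
            raise ValueError(f"{codon} is not a sense codon in table "
                             f"{code.table_id}")
    out = {}
    for aa, fam in code.families.items():
        total = sum(sense.get(c, 0) for c in fam)
        if total == 0:
            for c in fam:
                out[c] = float("nan")
            continue
        expected = total / len(fam)
        for c in fam:
            out[c] = sense.get(c, 0) / expected
    return out


def rscu_matrix(genomes, code: GeneticCode = INVERTEBRATE_MITO) -> pd.DataFrame:
    """One RSCU row per genome from its pooled PCG coding sequences.

    Genomes with no extractable PCG are skipped with a warning. Columns are
    the 62 sense codons grouped by amino acid.
    """
    rows = {}
    for g in genomes:
        cds_list = []
        for f in g.features:
            if f.cls != PCG:
                continue
            try:
                cds_list.append(extract_cds(g, f))
            except DegenerateCDSError as e:
                logger.warning("%s: skipping degenerate CDS (%s)", g.id, e)
        if not cds_list:
            logger.warning("%s: no extractable PCGs; row skipped", g.id)
            continue
        rows[g.id] = rscu(codon_counts(cds_list, code), code)
    if not rows:
        raise ValueError("no genome yielded an RSCU row")
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=list(code.sense_codons))
    df.index.name = "genome_id"
    return df


def log10_view(matrix: pd.DataFrame) -> pd.DataFrame:
    """log10 of the RSCU matrix with zero and missing cells masked (NaN),
    never -inf; a presentation transform for heatmaps."""
    with np.errstate(divide="ignore"):
        vals = np.log10(matrix.to_numpy(dtype=float))
    vals[~np.isfinite(vals)] = np.nan
    return pd.DataFrame(vals, index=matrix.index, columns=matrix.columns)


def rscu_pca(matrix: pd.DataFrame,
             n_components: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the species x codon RSCU matrix.

    Missing cells are imputed with the column mean; columns are centered but
    not variance-scaled; scores come from a full (deterministic) SVD with
    component signs fixed by forcing each component's largest-magnitude
    loading positive. Returns (scores, explained-variance fractions).
    """
    if matrix.shape[0] < 3:
        raise ValueError("PCA needs at least 3 genomes")
    X = matrix.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    if np.allclose(X, X[0], atol=1e-12):  # identical rows: no variance
        scores = np.zeros((X.shape[0], k))
        ratios = np.zeros(k)
    else:
        pca = PCA(n_components=k, svd_solver="full")
        scores = pca.fit_transform(X)
        for i in range(k):  # reproducible sign convention
            j = int(np.argmax(np.abs(pca.components_[i])))
            if pca.components_[i, j] < 0:
                scores[:, i] *= -1.0
        ratios = pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=matrix.index, columns=cols), ratios
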