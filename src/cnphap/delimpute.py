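"""Deletion-aware tri-allelic genotypes and a small-scale EM haplotype phaser.

A SNP lying inside a common deletion has three alleles per haplotype: the two
normal alleles A and B, plus the deletion allele O.  Observed diploid-style
calls recode as follows given the copy number of the deleted segment
(0, 1 or 2 surviving copies):

=========  =========  ==================
region CN  SNP call   tri-allelic pair
=========  =========  ==================
0          any        (O, O)
1          hom A      (A, O)
1          hom B      (B, O)
1          het        inconsistent
2          hom A/B    (A, A) / (B, B)
2          het        unknown (phase of A/B not observable)
=========  =========  ==================

The additive coding for association is the dosage #A - #B in [-2, 2]; O
contributes zero.  Unknown genotypes are imputed by a multi-marker EM phaser
that enumerates the haplotype space exhaustively (locus scale, <= 12 markers),
with the deletion allele atomic per haplotype across the deleted interval: a
haplotype is either O at every in-deletion marker or O at none.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "TriallelicGenotype",
    "HaplotypeFreqTable",
    "recode_in_deletion",
    "triallelic_dosage",
    "expected_dosage",
    "enumerate_haplotypes",
    "em_phase_triallelic",
]

ALLELES = ("A", "B", "O")


@dataclass(frozen=True)
class TriallelicGenotype:
    """Unordered allele pair over {A, B, O}, or unknown."""

    alleles: tuple[str, str] | None  # sorted pair, or None when unknown
    marker_id: str = ""
    inside_deletion: bool = True

    def __post_init__(self) -> None:
        if self.alleles is not None:
            if len(self.alleles) != 2 or any(a not in ALLELES for a in self.alleles):
                raise ValueError(f"invalid allele pair {self.alleles}")
            object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def unknown(self) -> bool:
        return self.alleles is None


def recode_in_deletion(snp_genotype: int, total_cn: int, marker_id: str = "") -> TriallelicGenotype:
    """Recode a diploid SNP call plus region copy number to a tri-allelic pair.

    ``snp_genotype`` counts B (alternate) alleles among the surviving copies,
    presented as an ordinary 0/1/2 call; ``total_cn`` is the copy number of
    the deleted segment (0..2).
    """
    if total_cn not in (0, 1, 2):
        raise ValueError("total_cn within the deleted region must be 0, 1 or 2")
    if snp_genotype not in (0, 1, 2):
        raise ValueError("snp_genotype must be 0, 1 or 2")
    if total_cn == 0:
        return TriallelicGenotype(("O", "O"), marker_id)
    if total_cn == 1:
        if snp_genotype == 0:
            return TriallelicGenotype(("A", "O"), marker_id)
        if snp_genotype == 2:
            return TriallelicGenotype(("B", "O"), marker_id)
        raise ValueError(
            "heterozygous diploid call with a single surviving copy is inconsistent"
        )
    if snp_genotype == 0:
        return TriallelicGenotype(("A", "A"), marker_id)
    if snp_genotype == 2:
        return TriallelicGenotype(("B", "B"), marker_id)
    return TriallelicGenotype(None, marker_id)  # het of normal alleles: phase unknown


def triallelic_dosage(g: TriallelicGenotype) -> int:
    """Integer dosage #A - #B for a known tri-allelic genotype."""
    if g.unknown:
        raise ValueError("unknown genotype has no integer dosage; supply a posterior")
    return g.alleles.count("A") - g.alleles.count("B")


def expected_dosage(posterior: dict[tuple[str, str], float]) -> float:
    """Expected #A - #B under a posterior over allele pairs."""
    total = sum(posterior.values())
    if total <= 0:
        raise ValueError("posterior weights must sum to a positive value")
    return sum(
        w * (pair.count("A") - pair.count("B")) for pair, w in posterior.items()
    ) / total


# ---------------------------------------------------------------------------
# exhaustive multi-marker EM phaser


def enumerate_haplotypes(n_markers: int, deletion_mask: np.ndarray) -> list[str]:
    """All haplotype strings over {A, B, O} with the deletion atomic.

    Markers flagged by ``deletion_mask`` are jointly either all O (the
    haplotype carries the deletion) or each A/B.  Markers outside the deletion
    are always A/B.
    """
    if n_markers > 12:
        raise ValueError("exhaustive phaser is limited to <= 12 markers")
    deletion_mask = np.asarray(deletion_mask, dtype=bool)
    out_idx = np.flatnonzero(~deletion_mask)
    haps = []
    for carries_del in (False, True) if deletion_mask.any() else (False,):
        free = out_idx if carries_del else np.arange(n_markers)
        for combo in product("AB", repeat=len(free)):
            h = ["O"] * n_markers
            for pos, a in zip(free, combo):
                h[pos] = a
            haps.append("".join(h))
    return haps


@dataclass
class HaplotypeFreqTable:
    """EM-fitted haplotype frequencies over {A, B, O} strings."""

    haplotypes: list[str]
    freqs: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool

    def as_dict(self, prune: float = 1e-6) -> dict[str, float]:
        return {
            h: float(f) for h, f in zip(self.haplotypes, self.freqs) if f >= prune
        }


def _compatible_pairs(
    genotypes: list[TriallelicGenotype | None],
    haps: list[str],
    total_cn: int | None,
) -> list[tuple[int, int]]:
    """Ordered haplotype-index pairs compatible with one individual's calls."""
    pairs = []
    for i, h1 in enumerate(haps):
        for j, h2 in enumerate(haps):
            if total_cn is not None:
                n_o = (1 if "O" in h1 else 0) + (1 if "O" in h2 else 0)
                if n_o != 2 - total_cn:
                    continue
            ok = True
            for m, g in enumerate(genotypes):
                if g is None or g.unknown:
                    continue
                if tuple(sorted((h1[m], h2[m]))) != g.alleles:
                    ok = False
                    break
            if ok:
                pairs.append((i, j))
    return pairs


def em_phase_triallelic(
    genotypes: list[list[TriallelicGenotype | None]],
    deletion_mask: np.ndarray,
    total_cn: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed=None,
) -> tuple[HaplotypeFreqTable, list[dict[tuple[str, str], float]]]:
    """Haplotype-frequency EM with exhaustive enumeration; imputes unknowns.

    ``genotypes[i][m]`` is individual i's call at marker m (None or unknown =
    missing, to be imputed).  ``total_cn`` optionally constrains the number of
    deletion-carrying haplotypes per individual to 2 - cn.  Returns the fitted
    frequency table and, per individual, a posterior over unordered haplotype
    string pairs.
    """
    n = len(genotypes)
    m = len(genotypes[0]) if n else 0
    deletion_mask = np.asarray(deletion_mask, dtype=bool)
    haps = enumerate_haplotypes(m, deletion_mask)
    H = len(haps)
    compat = []
    bad = []
    for i, row in enumerate(genotypes):
        cn_i = None if total_cn is None else int(total_cn[i])
        pairs = _compatible_pairs(row, haps, cn_i)
        if not pairs:
            bad.append(i)
        compat.append(np.array(pairs, dtype=int).reshape(-1, 2))
    if bad:
        raise ValueError(f"no compatible diplotype for individuals {bad}")
    # init: uniform over haplotypes appearing in any compatible pair
    seen = np.zeros(H, dtype=bool)
    for pairs in compat:
        seen[pairs.ravel()] = True
    p = seen / seen.sum()
    ll_prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        counts = np.zeros(H)
        ll = 0.0
        for pairs in compat:
            w = p[pairs[:, 0]] * p[pairs[:, 1]]
            tot = w.sum()
            ll += np.log(max(tot, 1e-300))
            w = w / max(tot, 1e-300)
            np.add.at(counts, pairs[:, 0], w)
            np.add.at(counts, pairs[:, 1], w)
        assert ll >= ll_prev - 1e-9 * max(1.0, abs(ll_prev)), "EM log-likelihood decreased"
        if np.isfinite(ll_prev) and ll - ll_prev < tol * max(1.0, abs(ll)):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
        p = counts / (2 * n)
    # per-individual posteriors over unordered pairs
    posteriors: list[dict[tuple[str, str], float]] = []
    for pairs in compat:
        w = p[pairs[:, 0]] * p[pairs[:, 1]]
        w = w / max(w.sum(), 1e-300)
        d: dict[tuple[str, str], float] = {}
        for (a, b), wi in zip(pairs, w):
            key = tuple(sorted((haps[a], haps[b])))
            d[key] = d.get(key, 0.0) + float(wi)
        posteriors.append(d)
    table = HaplotypeFreqTable(
        haplotypes=haps, freqs=p, log_likelihood=ll_prev, n_iter=it, converged=converged
    )
    return table, posteriors


def marker_posterior(
    pair_posterior: dict[tuple[str, str], float], marker: int
) -> dict[tuple[str, str], float]:
    """Marginal posterior over one marker's unordered allele pair."""
    out: dict[tuple[str, str], float] = {}
    for (h1, h2), w in pair_posterior.items():
        key = tuple(sorted((h1[marker], h2[marker])))
        out[key] = out.get(key, 0.0) + w
    return out
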