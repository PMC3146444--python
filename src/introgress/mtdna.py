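"""Haplotype collapsing and Nei diversity statistics for aligned mtDNA.

Works on pre-aligned haploid fragments (COI, COII, CYTB, 12S, ND1 style).
Sequences are collapsed to haplotypes, from which come the number of
segregating sites S, Nei's haplotype diversity

    h = n (1 − Σ p_i²) / (n − 1)

with its sampling variance

    V(h) = [2 / (n(n−1))] { 2(n−2) [Σ p³ − (Σ p²)²] + Σ p² − (Σ p²)² },

and nucleotide diversity π — the mean number of pairwise differences per
site over all unordered sequence pairs. Sites containing gaps or ambiguous
bases are excluded alignment-wide by default (complete-sites policy, the
DnaSP-like convention); pairwise deletion is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "HaploAlignment",
    "HaplotypeSpectrum",
    "read_fasta_alignment",
    "collapse_haplotypes",
    "haplotype_diversity",
    "nucleotide_diversity",
    "diversity_report",
]

_VALID_BASES = frozenset("ACGT")


@dataclass
class HaploAlignment:
    """Aligned haploid sequences with optional species/ecology labels."""

    ids: list[str]
    sequences: list[str]
    species: list[str] = field(default_factory=list)
    ecology: list[str] = field(default_factory=list)  # sympatric / allopatric

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment must contain at least one sequence")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        for attr in ("species", "ecology"):
            vals = getattr(self, attr)
            if vals and len(vals) != len(self.sequences):
                raise ValueError(f"{attr} labels differ in length from sequences")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])


def read_fasta_alignment(path: str | Path) -> HaploAlignment:
    """Read an aligned FASTA file into a :class:`HaploAlignment`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no sequences found")
    return HaploAlignment(
        ids=[r.id for r in records], sequences=[str(r.seq) for r in records]
    )


@dataclass
class HaplotypeSpectrum:
    """Haplotype counts with segregating sites and pairwise differences.

    ``counts[i]`` is the multiplicity of haplotype i (descending);
    ``diff_matrix[i, j]`` the number of differing retained sites between
    haplotypes i and j; ``retained_length`` the number of alignment columns
    the statistics were computed over.
    """

    counts: np.ndarray
    segregating_sites: int
    diff_matrix: np.ndarray
    haplotypes: list[str]
    retained_length: int

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_haplotypes(self) -> int:
        return len(self.counts)


def collapse_haplotypes(
    aln: HaploAlignment, site_policy: str = "complete_sites_only"
) -> HaplotypeSpectrum:
    """Group identical sequences into haplotypes and count differences.

    ``complete_sites_only`` drops every alignment column containing a gap
    or ambiguous base before comparing; ``pairwise`` keeps all columns and
    counts differences per pair only at sites where both sequences have an
    unambiguous base (S likewise ignores ambiguous states per column).
    """
    if site_policy not in ("complete_sites_only", "pairwise"):
        raise ValueError("site_policy must be 'complete_sites_only' or 'pairwise'")
    arr = np.array([list(s) for s in aln.sequences])
    ok = np.isin(arr, list(_VALID_BASES))

    if site_policy == "complete_sites_only":
        keep = ok.all(axis=0)
        if not keep.any():
            raise ValueError("no alignment columns without gaps/ambiguity remain")
        sub = arr[:, keep]
        seqs = ["".join(row) for row in sub]
        groups: dict[str, int] = {}
        for s in seqs:
            groups[s] = groups.get(s, 0) + 1
        haps = sorted(groups, key=lambda h: (-groups[h], h))
        counts = np.array([groups[h] for h in haps])
        hap_arr = np.array([list(h) for h in haps])
        nh = len(haps)
        diff = np.zeros((nh, nh), dtype=np.int64)
        for i in range(nh):
            for j in range(i + 1, nh):
                d = int((hap_arr[i] != hap_arr[j]).sum())
                diff[i, j] = diff[j, i] = d
        seg = int((sub != sub[0]).any(axis=0).sum())
        return HaplotypeSpectrum(
            counts=counts,
            segregating_sites=seg,
            diff_matrix=diff,
            haplotypes=haps,
            retained_length=int(keep.sum()),
        )

    # pairwise policy: group on the full sequence string, compare on
    # mutually unambiguous sites per pair
    groups = {}
    for s in aln.sequences:
        groups[s] = groups.get(s, 0) + 1
    haps = sorted(groups, key=lambda h: (-groups[h], h))
    counts = np.array([groups[h] for h in haps])
    hap_arr = np.array([list(h) for h in haps])
    hap_ok = np.isin(hap_arr, list(_VALID_BASES))
    nh = len(haps)
    diff = np.zeros((nh, nh), dtype=np.int64)
    for i in range(nh):
        for j in range(i + 1, nh):
            both = hap_ok[i] & hap_ok[j]
            d = int(((hap_arr[i] != hap_arr[j]) & both).sum())
            diff[i, j] = diff[j, i] = d
    seg = 0
    for col in range(arr.shape[1]):
        states = set(arr[ok[:, col], col])
        seg += len(states) > 1
    return HaplotypeSpectrum(
        counts=counts,
        segregating_sites=seg,
        diff_matrix=diff,
        haplotypes=haps,
        retained_length=arr.shape[1],
    )


def haplotype_diversity(spectrum: HaplotypeSpectrum) -> tuple[float, float]:
    """Nei's haplotype diversity h and its sampling standard deviation.

    Requires n ≥ 2 sequences; returns ``(h, sd)`` where sd is the square
    root of Nei's V(h) (see module docstring).
    """
    n = spectrum.n
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2 sequences")
    p = spectrum.counts / n
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    h = n * (1.0 - s2) / (n - 1)
    var = (2.0 / (n * (n - 1))) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return h, float(np.sqrt(max(var, 0.0)))


def nucleotide_diversity(
    spectrum: HaplotypeSpectrum, seq_length: int | None = None
) -> float:
    """Nucleotide diversity π per site.

    π = [Σ_{i<j over sequences} d_ij / C(n, 2)] / L, computed from the
    haplotype spectrum as Σ_{i≤j over haplotypes} n_i n_j d_ij weights
    (within-haplotype pairs contribute zero). ``seq_length`` defaults to
    the retained alignment length.
    """
    n = spectrum.n
    if n < 2:
        raise ValueError("nucleotide diversity requires n >= 2 sequences")
    L = spectrum.retained_length if seq_length is None else int(seq_length)
    if L < 1:
        raise ValueError("sequence length must be >= 1")
    c = spectrum.counts.astype(float)
    total = float(c @ spectrum.diff_matrix @ c) / 2.0  # i<j pairs, d symmetric
    return total / comb(n, 2) / L


def diversity_report(
    fragments: dict[str, HaploAlignment], site_policy: str = "complete_sites_only"
) -> pd.DataFrame:
    """Per-fragment summary: N, bp, S, h ± sd, π (5 decimals).

    ``fragments`` maps gene name to its alignment; the output mirrors the
    usual per-gene mitochondrial diversity table.
    """
    rows = []
    for gene, aln in fragments.items():
        spec = collapse_haplotypes(aln, site_policy)
        if spec.n >= 2:
            h, sd = haplotype_diversity(spec)
            pi = nucleotide_diversity(spec, aln.length)
        else:
            h = sd = pi = np.nan
        rows.append(
            {
                "gene": gene,
                "N": spec.n,
                "bp": aln.length,
                "n_haplotypes": spec.n_haplotypes,
                "S": spec.segregating_sites,
                "H": round(h, 3),
                "H_sd": round(sd, 3),
                "pi": round(pi, 5),
            }
        )
    return pd.DataFrame(rows).set_index("gene")
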