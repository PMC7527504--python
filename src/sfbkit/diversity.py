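"""Polymorphism and divergence statistics for coding alignments.

This module computes the classic descriptive popgen quantities for a
sample of aligned coding sequences:

* the site spectrum — segregating sites *S*, singleton and
  parsimony-informative site counts and the total mutation count
  :math:`\\eta` (per column, number of distinct states minus one);
* nucleotide diversity :math:`\\pi` (mean pairwise difference per site),
  optionally Jukes–Cantor corrected,
  :math:`d = -\\tfrac{3}{4}\\ln(1 - \\tfrac{4}{3}p)`;
* the Nei–Gojobori (1986) approximate partition of codons into expected
  synonymous and non-synonymous *sites*, and of codon differences into
  synonymous and non-synonymous *changes* via averaging over all
  mutational pathways between two codons;
* within-sample diversities at synonymous and non-synonymous sites
  (:math:`\\pi_S`, :math:`\\pi_A`) and per-site divergences against a
  designated comparator set (:math:`K_S`, :math:`K_A`).

Conventions (all overridable where a flag is documented):

* columns containing ``N`` exclude the affected sequences from that
  column's counts; per-site normalisation uses the pairwise-valid length;
* single-nucleotide changes that would create a stop codon are removed
  from the Nei–Gojobori possible-change set, so a codon adjacent to stops
  contributes slightly fewer than 3 sites;
* mutational pathways passing through a stop codon are excluded from
  pathway averaging; if every pathway is blocked the full set is used and
  a warning is logged;
* Jukes–Cantor correction is applied per pairwise comparison and the
  corrected values averaged, not applied to the averaged proportion.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from functools import lru_cache
from typing import Iterable

from .alignment import Alignment, CodonAlignment, STOP_CODONS, _STANDARD_TABLE

logger = logging.getLogger(__name__)

__all__ = [
    "SiteSpectrum",
    "NGSites",
    "DiversitySummary",
    "site_spectrum",
    "nucleotide_diversity",
    "jukes_cantor",
    "ng_site_counts",
    "ng_codon_differences",
    "classify_mutations",
    "pi_syn_nonsyn",
    "ka_ks",
    "diversity_summary",
    "diversity_table",
]

_AA = dict(_STANDARD_TABLE.forward_table)  # 61 sense codons -> amino acid
_NUCS = "ACGT"


# ---------------------------------------------------------------------------
# Site spectrum
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SiteSpectrum:
    """Counts of segregating-site classes over an alignment.

    ``eta`` is the total number of mutations, summing (distinct states − 1)
    over columns, so a triallelic column contributes two mutations but one
    segregating site.  A variable site is *parsimony informative* if at
    least two states are each carried by at least two sequences, and a
    *singleton site* otherwise, so ``singletons + parsimony_informative == S``.
    """

    S: int
    singletons: int
    parsimony_informative: int
    eta: int


def site_spectrum(aln: Alignment) -> SiteSpectrum:
    """Classify alignment columns into the segregating-site spectrum.

    Requires a gap-stripped nucleotide alignment with n >= 2.  Sequences
    carrying ``N`` at a column are excluded from that column's counts.
    """
    if aln.n < 2:
        raise ValueError("site spectrum requires at least 2 sequences")
    S = singles = par_inf = eta = 0
    for col in aln.columns():
        counts: dict[str, int] = {}
        for c in col:
            if c in _NUCS:
                counts[c] = counts.get(c, 0) + 1
        k = len(counts)
        if k < 2:
            continue
        S += 1
        eta += k - 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            par_inf += 1
        else:
            singles += 1
    return SiteSpectrum(S=S, singletons=singles, parsimony_informative=par_inf, eta=eta)


# ---------------------------------------------------------------------------
# Pairwise diversity
# ---------------------------------------------------------------------------

def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction of a difference proportion."""
    if p >= 0.75:
        raise ValueError(f"Jukes-Cantor correction undefined for p={p:.4f} >= 3/4")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _pairwise_p(a: str, b: str) -> tuple[int, int]:
    """(differences, compared length) over columns where both are ACGT."""
    diffs = valid = 0
    for x, y in zip(a, b):
        if x in _NUCS and y in _NUCS:
            valid += 1
            if x != y:
                diffs += 1
    return diffs, valid


def nucleotide_diversity(aln: Alignment, jc: bool = False) -> float:
    """Nucleotide diversity π: mean pairwise difference proportion.

    With ``jc=True`` each pairwise proportion is Jukes–Cantor corrected
    before averaging; a pairwise proportion >= 3/4 then raises.
    """
    if aln.n < 2:
        raise ValueError("nucleotide diversity requires at least 2 sequences")
    total = 0.0
    npairs = 0
    for r1, r2 in itertools.combinations(aln.records, 2):
        diffs, valid = _pairwise_p(r1.seq, r2.seq)
        if valid == 0:
            raise ValueError(f"no comparable sites between {r1.id!r} and {r2.id!r}")
        p = diffs / valid
        total += jukes_cantor(p) if jc else p
        npairs += 1
    return total / npairs


def mean_pairwise_differences(aln: Alignment) -> float:
    """Mean number of pairwise differences k̂ (absolute, not per site)."""
    if aln.n < 2:
        raise ValueError("requires at least 2 sequences")
    total = 0
    npairs = 0
    for r1, r2 in itertools.combinations(aln.records, 2):
        diffs, _ = _pairwise_p(r1.seq, r2.seq)
        total += diffs
        npairs += 1
    return total / npairs


# ---------------------------------------------------------------------------
# Nei–Gojobori site and difference counting
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class NGSites:
    """Expected synonymous / non-synonymous site counts (fractional)."""

    syn_sites: float
    nonsyn_sites: float

    @property
    def total(self) -> float:
        return self.syn_sites + self.nonsyn_sites


@lru_cache(maxsize=None)
def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Per-codon (syn, nonsyn) site counts; stop targets excluded.

    Each position contributes (synonymous changes)/3 synonymous sites and
    (non-synonymous non-stop changes)/3 non-synonymous sites, so a codon
    from which some single change would create a stop totals less than 3.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    aa = _AA[codon]
    syn = nonsyn = 0.0
    for pos in range(3):
        for alt in _NUCS:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            if _AA[mut] == aa:
                syn += 1.0 / 3.0
            else:
                nonsyn += 1.0 / 3.0
    return syn, nonsyn


def _usable_codon(codon: str) -> bool:
    return all(c in _NUCS for c in codon) and codon not in STOP_CODONS


def _seq_site_counts(codons: Iterable[str]) -> tuple[float, float]:
    s = n = 0.0
    for codon in codons:
        if _usable_codon(codon):
            cs, cn = _codon_site_counts(codon)
            s += cs
            n += cn
    return s, n


def ng_site_counts(codon_aln: CodonAlignment) -> NGSites:
    """Nei–Gojobori expected site counts averaged across all sequences.

    Codons containing ``N`` (or stops, when loaded with ``allow_stops``)
    are skipped for the affected sequence; a gap raises (strip first).
    """
    totals_s = totals_n = 0.0
    for i in range(codon_aln.n):
        codons = codon_aln.codons(i)
        for k, codon in enumerate(codons):
            if "-" in codon:
                raise ValueError(f"gap in codon {k + 1}; strip gap columns first")
        s, n = _seq_site_counts(codons)
        totals_s += s
        totals_n += n
    return NGSites(syn_sites=totals_s / codon_aln.n, nonsyn_sites=totals_n / codon_aln.n)


@lru_cache(maxsize=None)
def ng_codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (non-synonymous, synonymous) differences between codons.

    All orderings of the differing positions (1, 2 or 6) are walked from
    ``codon_a`` to ``codon_b``; each step is typed by amino-acid identity
    and the per-pathway counts averaged.  Pathways whose intermediate
    codons are stops are excluded; if that empties the set, all pathways
    are used and a warning logged.  ``Nd + Ns`` equals the number of
    differing positions.
    """
    if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
        raise ValueError("pathway counting requires stop-free codons")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return (0.0, 0.0)

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = codon_a
        nd = ns = 0
        for step, pos in enumerate(order):
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and step < len(order) - 1:
                return None  # pathway passes through a stop
            if nxt in STOP_CODONS:
                return None
            if _AA[cur] == _AA[nxt]:
                ns += 1
            else:
                nd += 1
            cur = nxt
        return (nd, ns)

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:
        logger.warning(
            "all mutational pathways between %s and %s pass through stop codons; "
            "including them anyway",
            codon_a,
            codon_b,
        )
        valid = []
        for order in itertools.permutations(diff_pos):
            cur = codon_a
            nd = ns = 0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                a1 = _AA.get(cur, "*")
                a2 = _AA.get(nxt, "*")
                if a1 == a2:
                    ns += 1
                else:
                    nd += 1
                cur = nxt
            valid.append((nd, ns))
    nd = sum(p[0] for p in valid) / len(valid)
    ns = sum(p[1] for p in valid) / len(valid)
    return (nd, ns)


def _pair_syn_nonsyn(
    codons_a: list[str], codons_b: list[str]
) -> tuple[float, float, float, float]:
    """(Nd, Ns, nonsyn_sites, syn_sites) for one sequence pair.

    Sites are averaged over the two sequences, restricted to codon
    columns usable in both.
    """
    nd = ns = 0.0
    syn_sites = nonsyn_sites = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if not (_usable_codon(ca) and _usable_codon(cb)):
            continue
        d_nd, d_ns = ng_codon_differences(ca, cb)
        nd += d_nd
        ns += d_ns
        sa, na = _codon_site_counts(ca)
        sb, nb = _codon_site_counts(cb)
        syn_sites += (sa + sb) / 2.0
        nonsyn_sites += (na + nb) / 2.0
    return nd, ns, nonsyn_sites, syn_sites


def _pair_ps_pa(codons_a: list[str], codons_b: list[str], jc: bool) -> tuple[float, float]:
    nd, ns, nonsyn_sites, syn_sites = _pair_syn_nonsyn(codons_a, codons_b)
    if syn_sites == 0 or nonsyn_sites == 0:
        raise ValueError("no synonymous or no non-synonymous sites in comparison")
    ps = ns / syn_sites
    pa = nd / nonsyn_sites
    if jc:
        ps = jukes_cantor(ps)
        pa = jukes_cantor(pa)
    return ps, pa


def pi_syn_nonsyn(codon_aln: CodonAlignment, jc: bool = False) -> tuple[float, float]:
    """Within-sample diversities (π_S, π_A) at synonymous / non-synonymous sites.

    For every sequence pair, synonymous and non-synonymous differences
    (pathway-averaged) are divided by the pair-averaged Nei–Gojobori site
    counts; the per-pair proportions (JC-corrected if requested) are then
    averaged over all pairs.
    """
    if codon_aln.n < 2:
        raise ValueError("requires at least 2 sequences")
    all_codons = [codon_aln.codons(i) for i in range(codon_aln.n)]
    ps_sum = pa_sum = 0.0
    npairs = 0
    for i, j in itertools.combinations(range(codon_aln.n), 2):
        ps, pa = _pair_ps_pa(all_codons[i], all_codons[j], jc)
        ps_sum += ps
        pa_sum += pa
        npairs += 1
    return ps_sum / npairs, pa_sum / npairs


def ka_ks(
    codon_aln: CodonAlignment,
    comparator: Alignment | None = None,
    jc: bool = True,
) -> tuple[float, float]:
    """Per-site synonymous / non-synonymous divergence (K_S, K_A).

    With a ``comparator`` alignment (e.g. ancestral or outgroup alleles,
    aligned to the same columns), divergence is the mean over all
    (focal, comparator) sequence pairs.  With ``comparator=None`` the
    intra-sample mode is used: mean over all focal pairs (identical to
    π_S/π_A on the same data).
    """
    focal = [codon_aln.codons(i) for i in range(codon_aln.n)]
    if comparator is None:
        ks, ka = pi_syn_nonsyn(codon_aln, jc=jc)
        return ks, ka
    if comparator.n < 1:
        raise ValueError("comparator alignment is empty")
    if comparator.length != codon_aln.alignment.length:
        raise ValueError("comparator must be aligned to the same columns")
    comp = CodonAlignment(comparator, frame_offset=codon_aln.frame_offset,
                          allow_stops=True)
    others = [comp.codons(i) for i in range(comp.n)]
    ks_sum = ka_sum = 0.0
    npairs = 0
    for f in focal:
        for o in others:
            ps, pa = _pair_ps_pa(f, o, jc)
            ks_sum += ps
            ka_sum += pa
            npairs += 1
    return ks_sum / npairs, ka_sum / npairs


# ---------------------------------------------------------------------------
# Mutation classification (shared with the neutrality module)
# ---------------------------------------------------------------------------

def largest_remainder_round(values: Iterable[float]) -> list[int]:
    """Round non-negative floats to integers preserving the rounded total.

    The target total is the sum rounded to the nearest integer; floors are
    taken first and the remaining units assigned by largest fractional
    part (ties broken by position, first wins).
    """
    vals = list(values)
    target = round(sum(vals))
    floors = [math.floor(v) for v in vals]
    rem = target - sum(floors)
    order = sorted(range(len(vals)), key=lambda i: (-(vals[i] - floors[i]), i))
    out = floors[:]
    for i in order[:rem]:
        out[i] += 1
    return out


def classify_mutations(codon_aln: CodonAlignment) -> tuple[float, float]:
    """Fractional (synonymous, non-synonymous) polymorphic mutation counts.

    For each variable codon column the modal codon (ties broken
    lexicographically, so the result is invariant to sequence order) is
    the reference; every other distinct codon contributes its
    pathway-averaged differences once.  Codons containing ``N`` or stops
    are ignored.  Use :func:`largest_remainder_round` for integer reports.
    """
    syn = nonsyn = 0.0
    for k in range(codon_aln.n_codons):
        col = [c for c in codon_aln.codon_column(k) if _usable_codon(c)]
        if len(col) < 2:
            continue
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        if len(counts) < 2:
            continue
        ref = max(counts, key=lambda c: (counts[c], c))  # modal; lexic. tie-break
        for codon in counts:
            if codon == ref:
                continue
            nd, ns = ng_codon_differences(ref, codon)
            syn += ns
            nonsyn += nd
    return syn, nonsyn


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DiversitySummary:
    """One summary row for a sample of coding sequences.

    ``K_S``/``K_A`` are ``None`` when no comparator was supplied.
    """

    name: str
    n: int
    spectrum: SiteSpectrum
    pi: float
    syn_mut: int
    nonsyn_mut: int
    pi_S: float
    pi_A: float
    K_S: float | None
    K_A: float | None
    jc_corrected: bool

    @property
    def pi_ratio(self) -> float | None:
        return self.pi_A / self.pi_S if self.pi_S > 0 else None

    @property
    def k_ratio(self) -> float | None:
        if self.K_S is None or self.K_A is None or self.K_S == 0:
            return None
        return self.K_A / self.K_S


def diversity_summary(
    codon_aln: CodonAlignment,
    comparator: Alignment | None = None,
    jc: bool = True,
    name: str = "sample",
) -> DiversitySummary:
    """Compute the full diversity summary row for one allele class."""
    aln = codon_aln.alignment
    spec = site_spectrum(aln)
    pi = nucleotide_diversity(aln, jc=jc)
    syn_f, nonsyn_f = classify_mutations(codon_aln)
    syn_i, nonsyn_i = largest_remainder_round([syn_f, nonsyn_f])
    pi_s, pi_a = pi_syn_nonsyn(codon_aln, jc=jc)
    if comparator is not None:
        k_s, k_a = ka_ks(codon_aln, comparator, jc=jc)
    else:
        k_s = k_a = None
    return DiversitySummary(
        name=name,
        n=aln.n,
        spectrum=spec,
        pi=pi,
        syn_mut=syn_i,
        nonsyn_mut=nonsyn_i,
        pi_S=pi_s,
        pi_A=pi_a,
        K_S=k_s,
        K_A=k_a,
        jc_corrected=jc,
    )


_TABLE_COLUMNS = [
    "Name", "N", "Poly.S", "Sing", "Par.Inf", "pi", "M", "Syn.M", "N.Syn.M",
    "piS", "piA", "piA/piS", "KS", "KA", "KA/KS",
]


def _fmt(x: float | None, nd: int) -> str:
    return "NA" if x is None else f"{x:.{nd}f}"


def diversity_table(rows: Iterable[DiversitySummary]) -> str:
    """Render summary rows as a TSV table (π-family 3 dp, ratios 2 dp)."""
    lines = ["\t".join(_TABLE_COLUMNS)]
    for r in rows:
        sp = r.spectrum
        lines.append("\t".join([
            r.name, str(r.n), str(sp.S), str(sp.singletons),
            str(sp.parsimony_informative), _fmt(r.pi, 3), str(sp.eta),
            str(r.syn_mut), str(r.nonsyn_mut), _fmt(r.pi_S, 3), _fmt(r.pi_A, 3),
            _fmt(r.pi_ratio, 2), _fmt(r.K_S, 3), _fmt(r.K_A, 3),
            _fmt(r.k_ratio, 2),
        ]))
    return "\n".join(lines) + "\n"
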