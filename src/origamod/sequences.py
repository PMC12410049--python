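"""Orthogonal sticky-end design: cross-talk scoring and duplex thermodynamics.

Bond modules are 5-7 nt sticky ends.  Specificity requires that every
*unintended* pairing among the emitted sequences (a sequence against any
non-partner, against partners of other bonds, and against its own copy) can
form at most a short complementary run, while every *intended* duplex is a
perfect reverse-complement pair with a binding free energy close to the
rest of the set, so that all bonds of a design melt together.

Cross-talk between two strands, both written 5'→3', is the length of the
longest contiguous antiparallel complementary run over all relative
offsets; this equals the longest common substring of ``a`` and the reverse
complement of ``b``.  Duplex free energies come from the unified
nearest-neighbor stacking parameters (via Biopython's tables) with a
monovalent-equivalent salt correction for Mg²⁺.

The generator is a seeded stochastic search; correctness is defined by the
independent exhaustive verifier :func:`verify_orthogonal_set`, which scans
every ordered pair of emitted strands.
"""

from __future__ import annotations

import math
import random
import string
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "SaltModel",
    "DuplexThermo",
    "StickyEnd",
    "OrthogonalSet",
    "OrthogonalityReport",
    "OrthogonalSearchError",
    "reverse_complement",
    "nn_free_energy",
    "cross_talk",
    "generate_orthogonal_set",
    "verify_orthogonal_set",
]

_ALPHABET = set("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Unified nearest-neighbor ΔH (kcal/mol), ΔS (cal/mol/K) per stack + ends.
_NN_TABLE = _mt.DNA_NN3

REFERENCE_TEMPERATURE_K = 298.15


def _check_seq(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)} in sequence {seq!r}")
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string, 5'→3' in, 5'→3' out."""
    return str(Seq(_check_seq(seq)).reverse_complement())


@dataclass(frozen=True)
class SaltModel:
    """Ionic conditions for the entropy salt correction.

    Mg²⁺ is folded into a monovalent equivalent,
    [Na⁺]_eq = [Na⁺] + mg_equivalence·sqrt([Mg²⁺]) (molar), and the
    nearest-neighbor entropy is corrected by 0.368·(N−1)·ln[Na⁺]_eq
    cal/(mol·K).  Defaults match the assembly buffer (5 mM NaCl,
    20 mM MgCl₂); the equivalence factor is a first-order approximation
    and is exposed for override.
    """

    na_mM: float = 5.0
    mg_mM: float = 20.0
    mg_equivalence: float = 3.3

    @property
    def monovalent_equivalent_M(self) -> float:
        return self.na_mM / 1000.0 + self.mg_equivalence * math.sqrt(
            self.mg_mM / 1000.0
        )

    def describe(self) -> str:
        return (
            f"{self.na_mM:g} mM Na+, {self.mg_mM:g} mM Mg2+ "
            f"(~{self.monovalent_equivalent_M:.2f} M monovalent equivalent)"
        )


DEFAULT_SALT = SaltModel()


@dataclass(frozen=True)
class DuplexThermo:
    """Binding free energy of a perfect duplex at stated conditions."""

    delta_G: float  # kcal/mol
    temperature: float  # K
    salt_model: str


def _nn_step(dinuc: str) -> tuple[float, float]:
    comp = "".join(_COMPLEMENT[c] for c in dinuc)
    key = f"{dinuc}/{comp}"
    if key in _NN_TABLE:
        return _NN_TABLE[key]
    flipped = comp[::-1] + "/" + dinuc[::-1]
    return _NN_TABLE[flipped]


def nn_free_energy(
    seq: str,
    temperature: float = REFERENCE_TEMPERATURE_K,
    salt: SaltModel = DEFAULT_SALT,
    terminal_at_penalty: bool = True,
) -> float:
    """ΔG (kcal/mol) of the perfect duplex of ``seq`` with its complement.

    Sum of nearest-neighbor stacking ΔH/ΔS terms plus duplex initiation
    (terminal A·T vs G·C terms when ``terminal_at_penalty``), evaluated at
    ``temperature`` with the salt-corrected entropy.  More negative is
    stronger; a perfect duplex always has ΔG < 0 at these conditions.
    """
    seq = _check_seq(seq)
    if len(seq) < 2:
        raise ValueError("duplex needs at least 2 nucleotides")
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    dH = dS = 0.0
    for i in range(len(seq) - 1):
        h, s = _nn_step(seq[i : i + 2])
        dH += h
        dS += s
    if terminal_at_penalty:
        for end in (seq[0], seq[-1]):
            key = "init_G/C" if end in "GC" else "init_A/T"
            h, s = _NN_TABLE[key]
            dH += h
            dS += s
    dS += 0.368 * (len(seq) - 1) * math.log(salt.monovalent_equivalent_M)
    return dH - temperature * dS / 1000.0


def duplex_thermo(
    seq: str,
    temperature: float = REFERENCE_TEMPERATURE_K,
    salt: SaltModel = DEFAULT_SALT,
) -> DuplexThermo:
    return DuplexThermo(
        delta_G=nn_free_energy(seq, temperature, salt),
        temperature=temperature,
        salt_model=salt.describe(),
    )


def cross_talk(seq_a: str, seq_b: str) -> int:
    """Longest contiguous antiparallel complementary run between two strands.

    Both strands are taken 5'→3'; the score is the longest common substring
    of ``seq_a`` and reverse_complement(``seq_b``), i.e. the longest stretch
    over all relative offsets in which the two strands could zip up.
    Symmetric; equals len(a) for a against its own reverse complement; 0
    when no complementary dinucleotide (or single pair) aligns.
    """
    a = _check_seq(seq_a)
    b = reverse_complement(seq_b)
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


@dataclass(frozen=True)
class StickyEnd:
    """A labelled sticky-end strand; its partner is the reverse complement."""

    label: str
    sequence: str
    partner_label: str

    def __post_init__(self) -> None:
        seq = _check_seq(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not 5 <= len(seq) <= 7:
            raise ValueError(f"sticky end length {len(seq)} outside [5, 7]")


@dataclass
class OrthogonalityReport:
    """Outcome of the exhaustive pairwise verification of a sticky-end set."""

    violations: list[str] = field(default_factory=list)
    max_cross_talk_found: int = 0
    dG_spread_by_length: dict[int, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.violations


class OrthogonalSearchError(RuntimeError):
    """Search exhausted without satisfying the constraints."""

    def __init__(self, message: str, best_found: "OrthogonalSet", report: OrthogonalityReport):
        super().__init__(message)
        self.best_found = best_found
        self.report = report


@dataclass
class OrthogonalSet:
    """A set of sticky-end pairs with shared thermodynamic conditions."""

    ends: list[StickyEnd]
    temperature: float
    salt: SaltModel

    @property
    def pairs(self) -> list[tuple[StickyEnd, StickyEnd]]:
        by_label = {e.label: e for e in self.ends}
        out, seen = [], set()
        for e in self.ends:
            if e.label in seen or e.partner_label in seen:
                continue
            out.append((e, by_label[e.partner_label]))
            seen.update({e.label, e.partner_label})
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "label": e.label,
                "sequence": e.sequence,
                "partner": e.partner_label,
                "length": len(e.sequence),
                "delta_G_kcal_mol": nn_free_energy(
                    e.sequence, self.temperature, self.salt
                ),
            }
            for e in self.ends
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.ends:
                fh.write(f">{e.label}\n{e.sequence}\n")


def _default_labels(n: int) -> list[str]:
    letters = string.ascii_uppercase
    out = []
    for i in range(n):
        lab = letters[i % 26]
        if i >= 26:
            lab += str(i // 26)
        out.append(lab)
    return out


def verify_orthogonal_set(
    ends: Sequence[StickyEnd],
    max_crosstalk: int = 3,
    dG_window: float = 1.0,
    temperature: float = REFERENCE_TEMPERATURE_K,
    salt: SaltModel = DEFAULT_SALT,
) -> OrthogonalityReport:
    """Exhaustively verify a sticky-end set, independently of the search.

    Scans every ordered pair of emitted strands (including each strand
    against its own copy) with a direct all-offset antiparallel scan,
    skipping only intended partner duplexes; checks partner sequences are
    exact reverse complements, labels unique, no strand self-complementary,
    and intended duplex ΔG within ``dG_window`` of the per-length median.
    """
    report = OrthogonalityReport()
    by_label = {e.label: e for e in ends}
    if len(by_label) != len(ends):
        report.violations.append("duplicate labels in set")
    for e in ends:
        p = by_label.get(e.partner_label)
        if p is None:
            report.violations.append(f"{e.label}: partner {e.partner_label} missing")
        elif p.sequence != reverse_complement(e.sequence):
            report.violations.append(
                f"{e.label}/{p.label}: partner is not the reverse complement"
            )
        if e.sequence == reverse_complement(e.sequence):
            report.violations.append(f"{e.label}: self-complementary sequence")

    def longest_run(a: str, b: str) -> int:
        # direct offset scan: slide reversed b along a, count complement runs
        rb = b[::-1]
        best = 0
        for offset in range(-(len(rb) - 1), len(a)):
            run = 0
            for j, cb in enumerate(rb):
                i = offset + j
                if 0 <= i < len(a) and _COMPLEMENT[cb] == a[i]:
                    run += 1
                    best = max(best, run)
                else:
                    run = 0
        return best

    for ea in ends:
        for eb in ends:
            if eb.label == ea.partner_label:
                continue  # intended duplex
            run = longest_run(ea.sequence, eb.sequence)
            report.max_cross_talk_found = max(report.max_cross_talk_found, run)
            if run > max_crosstalk:
                report.violations.append(
                    f"cross-talk {ea.label} vs {eb.label}: run {run} > {max_crosstalk}"
                )
    for length in sorted({len(e.sequence) for e in ends}):
        dgs = [
            nn_free_energy(e.sequence, temperature, salt)
            for e in ends
            if len(e.sequence) == length
        ]
        med = sorted(dgs)[len(dgs) // 2]
        spread = max(abs(g - med) for g in dgs)
        report.dG_spread_by_length[length] = spread
        if spread > dG_window:
            report.violations.append(
                f"dG window: {length}-mers spread {spread:.2f} > {dG_window} kcal/mol"
            )
    return report


def generate_orthogonal_set(
    n_bonds: int,
    length: Union[int, Sequence[int]] = 5,
    dG_window: float = 1.0,
    max_crosstalk: int = 3,
    seed: int = 0,
    temperature: float = REFERENCE_TEMPERATURE_K,
    salt: SaltModel = DEFAULT_SALT,
    labels: Optional[Sequence[str]] = None,
    max_attempts: int = 50_000,
) -> OrthogonalSet:
    """Generate ``n_bonds`` orthogonal sticky-end pairs.

    Seeded stochastic generate-and-test: candidate strands are grown base
    by base so that no (max_crosstalk+1)-mer window collides with (or
    complements) any window already committed to the set — the condition
    equivalent to every unintended pairwise run being ≤ ``max_crosstalk``.
    Within each length class, intended-duplex ΔG values are held inside
    ``dG_window`` by anchoring to the first accepted member.  The emitted
    set is re-checked with :func:`verify_orthogonal_set`; on an exhausted
    search an :class:`OrthogonalSearchError` carries the best partial set
    and its verification report.  Fixed seed → byte-identical output.
    """
    if n_bonds < 1:
        raise ValueError("n_bonds must be >= 1")
    lengths = (
        [int(length)] * n_bonds if isinstance(length, int) else [int(l) for l in length]
    )
    if len(lengths) != n_bonds:
        raise ValueError("length list must have n_bonds entries")
    if any(not 5 <= l <= 7 for l in lengths):
        raise ValueError("sticky-end lengths must be in [5, 7]")
    if labels is None:
        labels = _default_labels(n_bonds)
    if len(set(labels)) != n_bonds:
        raise ValueError("labels must be unique, one per bond")

    k = max_crosstalk + 1

    def windows(s: str) -> list[str]:
        if len(s) < k:
            return []
        return [s[i : i + k] for i in range(len(s) - k + 1)]

    def grow(rng: random.Random, L: int, used: set[str], blocked: set[str]) -> Optional[str]:
        s = ""
        local: set[str] = set()
        while len(s) < L:
            options = list("ACGT")
            rng.shuffle(options)
            placed = False
            for b in options:
                t = s + b
                if len(t) >= k:
                    w = t[-k:]
                    rc_w = reverse_complement(w)
                    if (
                        w in used
                        or w in blocked
                        or w == rc_w
                        or rc_w in local
                        or w in local  # no window reuse across or within strands
                    ):
                        continue
                    s = t
                    local.add(w)
                else:
                    s = t
                placed = True
                break
            if not placed:
                return None
        if s == reverse_complement(s):
            return None
        return s

    # tightest (shortest) length class first: it has the fewest k-mer
    # windows per strand and crowds fastest
    order = sorted(range(n_bonds), key=lambda i: lengths[i])
    n_restarts = 10
    budget = max(1, max_attempts // n_restarts)
    accepted: list[tuple[str, int, str]] = []  # (label, length, sequence)
    attempts_total = 0
    for restart in range(n_restarts):
        rng = random.Random(f"{seed}:{restart}")
        used: set[str] = set()  # k-mer windows of all accepted primaries
        blocked: set[str] = set()  # their reverse complements
        bounds: dict[int, tuple[float, float]] = {}  # length -> ΔG (min, max)
        trial: list[tuple[str, int, str]] = []
        attempts = 0
        for idx in order:
            L = lengths[idx]
            done = False
            while attempts < budget:
                attempts += 1
                cand = grow(rng, L, used, blocked)
                if cand is None:
                    continue
                dg = nn_free_energy(cand, temperature, salt)
                if L in bounds:
                    lo, hi = bounds[L]
                    if max(hi, dg) - min(lo, dg) > dG_window:
                        continue
                    bounds[L] = (min(lo, dg), max(hi, dg))
                else:
                    gc = sum(c in "GC" for c in cand) / L
                    if not 0.3 <= gc <= 0.7:
                        continue
                    bounds[L] = (dg, dg)
                trial.append((labels[idx], L, cand))
                for w in windows(cand):
                    used.add(w)
                    blocked.add(reverse_complement(w))
                done = True
                break
            if not done:
                break
        attempts_total += attempts
        if len(trial) > len(accepted):
            accepted = trial
        if len(trial) == n_bonds:
            break
    attempts = attempts_total

    ends: list[StickyEnd] = []
    got = {lab for lab, _, _ in accepted}
    for idx in range(n_bonds):
        lab = labels[idx]
        if lab not in got:
            continue
        seq = next(s for l, _, s in accepted if l == lab)
        ends.append(StickyEnd(lab, seq, lab + "*"))
        ends.append(StickyEnd(lab + "*", reverse_complement(seq), lab))
    oset = OrthogonalSet(ends=ends, temperature=temperature, salt=salt)
    report = verify_orthogonal_set(
        ends, max_crosstalk, dG_window, temperature, salt
    )
    if len(got) < n_bonds or not report.ok:
        missing = [labels[i] for i in range(n_bonds) if labels[i] not in got]
        raise OrthogonalSearchError(
            f"orthogonal search exhausted after {attempts} attempts "
            f"(missing bonds: {missing or 'none'}; "
            f"violations: {len(report.violations)})",
            best_found=oset,
            report=report,
        )
    return oset
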