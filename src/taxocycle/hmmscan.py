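"""Profile HMM parsing and local Viterbi scoring.

Profile HMMs model a protein family as a chain of match states with
position-specific emission probabilities, flanked by insert and delete
states.  A sequence is scored in log2-odds ("bits") against a background
residue distribution: positive scores mean the sequence looks more like
the family than like random background.

The scoring mode implemented here is *unihit local over match states*: a
single contiguous run through the match-state chain, entered and exited
at any match state at zero cost.  There is no multihit J state and no
explicit begin/end entry distribution.  This keeps the dynamic program
exact and desk-verifiable; :func:`brute_force_score` enumerates every
legal path for small models and is used as an independent oracle.
Scoring is a replaceable component behind :func:`call_hits`, so a full
HMMER-compatible backend can be swapped in without touching callers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "AMBIGUITY_CODES",
    "ProfileHMM",
    "HmmHit",
    "HmmFormatError",
    "ScoringError",
    "parse_hmm_file",
    "write_hmm_file",
    "viterbi_score",
    "brute_force_score",
    "call_hits",
    "present_profiles",
    "read_fasta",
    "read_cutoff_table",
    "write_hits_tsv",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
#: Ambiguity codes scored with log-odds 0 (background-equal).
AMBIGUITY_CODES = frozenset("BZX")

# Column order of the per-node transition block, matching HMMER3 ASCII.
_T_MM, _T_MI, _T_MD, _T_IM, _T_II, _T_DM, _T_DD = range(7)

_NEG_INF = float("-inf")


class HmmFormatError(ValueError):
    """Raised when a HMMER3 ASCII file cannot be parsed."""


class ScoringError(ValueError):
    """Raised for sequences or models that cannot be scored."""


@dataclass
class ProfileHMM:
    """A profile HMM with match/insert/delete architecture.

    ``transitions`` has one row per node 0..M in HMMER column order
    (m->m, m->i, m->d, i->m, i->i, d->m, d->d); row ``k`` holds the
    probabilities out of node ``k`` toward node ``k+1``.  Row 0 is the
    begin node; it is parsed and written for format fidelity but unused
    by the zero-cost-entry scorer.
    """

    name: str
    length: int
    match_emissions: np.ndarray  # (M, 20) probabilities
    insert_emissions: np.ndarray  # (M, 20) probabilities
    transitions: np.ndarray  # (M+1, 7) probabilities
    background: np.ndarray  # (20,) probabilities
    accession: str | None = None
    cutoff_bits: float | None = None
    _tables: tuple | None = field(default=None, repr=False, compare=False)

    def validate(self, tol: float = 1e-6) -> None:
        if self.length < 1:
            raise HmmFormatError(f"{self.name}: model length must be >= 1")
        if self.match_emissions.shape != (self.length, 20):
            raise HmmFormatError(f"{self.name}: match emission table has wrong shape")
        if self.insert_emissions.shape != (self.length, 20):
            raise HmmFormatError(f"{self.name}: insert emission table has wrong shape")
        if self.transitions.shape != (self.length + 1, 7):
            raise HmmFormatError(f"{self.name}: transition table has wrong shape")
        for label, rows in (("match", self.match_emissions), ("insert", self.insert_emissions)):
            sums = rows.sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > tol)[0]
            if bad.size:
                raise HmmFormatError(
                    f"{self.name}: {label} emission row {bad[0] + 1} sums to {sums[bad[0]]:.8f}"
                )
        groups = {
            "match": self.transitions[:, [_T_MM, _T_MI, _T_MD]],
            "insert": self.transitions[:, [_T_IM, _T_II]],
            "delete": self.transitions[:, [_T_DM, _T_DD]],
        }
        for label, cols in groups.items():
            sums = cols.sum(axis=1)
            # A group may sum to 0 when the state is unreachable (all "*").
            bad = np.where((np.abs(sums - 1.0) > tol) & (np.abs(sums) > tol))[0]
            if bad.size:
                raise HmmFormatError(
                    f"{self.name}: {label} transition group at node {bad[0]} "
                    f"sums to {sums[bad[0]]:.8f}"
                )
        if np.any(self.background <= 0):
            raise HmmFormatError(f"{self.name}: background must be strictly positive")

    def scoring_tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Log2-odds emissions and log2 transitions, cached on the profile."""
        if self._tables is None:
            with np.errstate(divide="ignore"):
                mlo = np.log2(self.match_emissions / self.background)
                ilo = np.log2(self.insert_emissions / self.background)
                tlog = np.log2(self.transitions)
            self._tables = (mlo, ilo, tlog)
        return self._tables


@dataclass(frozen=True)
class HmmHit:
    sequence_id: str
    profile_name: str
    bit_score: float
    span_start: int  # 1-based inclusive on the input sequence; 0 if no alignment
    span_end: int
    passed: bool


# ---------------------------------------------------------------------------
# HMMER3 ASCII i/o
# ---------------------------------------------------------------------------

def _prob(token: str, lineno: int) -> float:
    if token == "*":
        return 0.0
    try:
        return math.exp(-float(token))
    except ValueError as exc:
        raise HmmFormatError(f"line {lineno}: bad probability token {token!r}") from exc


def _nll(p: float) -> str:
    # 9 decimals so parse(write(hmm)) reproduces probabilities within 1e-9
    return "*" if p <= 0.0 else f"{-math.log(p):.9f}"


def parse_hmm_file(path: str | Path) -> list[ProfileHMM]:
    """Parse one or more concatenated HMMER3 ASCII models.

    Stored values are negative natural logs of probabilities; ``*`` means
    probability zero.  A GA (gathering) cutoff line, when present,
    populates ``cutoff_bits`` with its sequence-level value.
    """
    lines = Path(path).read_text().splitlines()
    models: list[ProfileHMM] = []
    i = 0
    n = len(lines)
    while i < n:
        # skip blank lines between models
        while i < n and not lines[i].strip():
            i += 1
        if i >= n:
            break
        header = lines[i]
        if not header.startswith("HMMER3/"):
            raise HmmFormatError(f"line {i + 1}: expected HMMER3 format header, got {header!r}")
        i += 1
        name = acc = None
        length = None
        cutoff = None
        col_order: str | None = None
        while i < n:
            line = lines[i]
            if line.startswith("HMM "):
                toks = line.split()
                col_order = "".join(toks[1:])
                if len(col_order) != 20 or set(col_order) != set(AMINO_ACIDS):
                    raise HmmFormatError(f"line {i + 1}: unsupported alphabet {col_order!r}")
                i += 2  # skip the transition-header line
                break
            toks = line.split()
            if not toks:
                i += 1
                continue
            key = toks[0]
            if key == "NAME":
                name = toks[1]
            elif key == "ACC":
                acc = toks[1]
            elif key == "LENG":
                length = int(toks[1])
            elif key == "ALPH" and toks[1].lower() != "amino":
                raise HmmFormatError(f"line {i + 1}: only amino alphabets are supported")
            elif key == "GA":
                cutoff = float(toks[1].rstrip(";"))
            i += 1
        if name is None:
            raise HmmFormatError(f"model starting near line {i}: missing NAME")
        if length is None:
            raise HmmFormatError(f"model {name}: missing LENG")
        if col_order is None:
            raise HmmFormatError(f"model {name}: missing HMM emission header")
        perm = [col_order.index(aa) for aa in AMINO_ACIDS]

        background = np.full(20, 1.0 / 20.0)
        if i < n and lines[i].split() and lines[i].split()[0] == "COMPO":
            toks = lines[i].split()[1:]
            if len(toks) != 20:
                raise HmmFormatError(f"line {i + 1}: COMPO row needs 20 values")
            background = np.array([_prob(t, i + 1) for t in toks])[perm]
            i += 1
        # node 0: insert emissions + transitions (kept only for fidelity)
        i += 1  # insert0 emissions
        node0 = lines[i].split()
        if len(node0) != 7:
            raise HmmFormatError(f"line {i + 1}: node-0 transition row needs 7 values")
        transitions = np.zeros((length + 1, 7))
        transitions[0] = [_prob(t, i + 1) for t in node0]
        i += 1

        match = np.zeros((length, 20))
        insert = np.zeros((length, 20))
        for k in range(1, length + 1):
            if i >= n:
                raise HmmFormatError(f"model {name}: truncated at node {k}")
            toks = lines[i].split()
            if not toks or toks[0] != str(k):
                raise HmmFormatError(f"line {i + 1}: expected node {k}, got {toks[:1]}")
            if len(toks) < 21:
                raise HmmFormatError(f"line {i + 1}: match emission row of wrong arity")
            match[k - 1] = np.array([_prob(t, i + 1) for t in toks[1:21]])[perm]
            i += 1
            toks = lines[i].split()
            if len(toks) != 20:
                raise HmmFormatError(f"line {i + 1}: insert emission row of wrong arity")
            insert[k - 1] = np.array([_prob(t, i + 1) for t in toks])[perm]
            i += 1
            toks = lines[i].split()
            if len(toks) != 7:
                raise HmmFormatError(f"line {i + 1}: transition row needs 7 values")
            transitions[k] = [_prob(t, i + 1) for t in toks]
            i += 1
        if i >= n or lines[i].strip() != "//":
            raise HmmFormatError(f"model {name}: missing // end marker near line {i + 1}")
        i += 1
        hmm = ProfileHMM(
            name=name,
            accession=acc,
            length=length,
            match_emissions=match,
            insert_emissions=insert,
            transitions=transitions,
            background=background,
            cutoff_bits=cutoff,
        )
        # files store 5+ decimal nats; allow that quantization noise
        hmm.validate(tol=1e-4)
        models.append(hmm)
    if not models:
        raise HmmFormatError(f"{path}: no models found")
    return models


def write_hmm_file(profiles: Sequence[ProfileHMM], path: str | Path) -> Path:
    """Write profiles as concatenated HMMER3/f ASCII (round-trips via parse)."""
    path = Path(path)
    out: list[str] = []
    for p in profiles:
        out.append("HMMER3/f [3.4 | taxocycle]")
        out.append(f"NAME  {p.name}")
        if p.accession:
            out.append(f"ACC   {p.accession}")
        out.append(f"LENG  {p.length}")
        out.append("ALPH  amino")
        out.append("RF    no")
        out.append("MM    no")
        out.append("CONS  yes")
        out.append("CS    no")
        out.append("MAP   yes")
        if p.cutoff_bits is not None:
            out.append(f"GA    {p.cutoff_bits:.2f} {p.cutoff_bits:.2f};")
        out.append("HMM     " + "".join(f"{aa:>13}" for aa in AMINO_ACIDS))
        out.append(
            "        "
            + "".join(f"{t:>13}" for t in ("m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d"))
        )
        bg_row = "".join(f"{_nll(v):>13}" for v in p.background)
        out.append(f"  COMPO {bg_row}")
        out.append("        " + bg_row)  # node-0 insert emissions
        out.append("        " + "".join(f"{_nll(v):>13}" for v in p.transitions[0]))
        for k in range(1, p.length + 1):
            cons = AMINO_ACIDS[int(np.argmax(p.match_emissions[k - 1]))]
            ems = "".join(f"{_nll(v):>13}" for v in p.match_emissions[k - 1])
            out.append(f"{k:>7} {ems} {k:>6} {cons.lower()} - - -")
            out.append("        " + "".join(f"{_nll(v):>13}" for v in p.insert_emissions[k - 1]))
            out.append("        " + "".join(f"{_nll(v):>13}" for v in p.transitions[k]))
        out.append("//")
    path.write_text("\n".join(out) + "\n")
    return path


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _filter_sequence(sequence: str) -> tuple[list[str], list[int]]:
    """Uppercase, drop ``*`` stops, reject non-alphabet characters.

    Returns residues plus their 1-based positions in the original string.
    """
    if not sequence:
        raise ScoringError("empty sequence")
    residues: list[str] = []
    positions: list[int] = []
    for pos, ch in enumerate(sequence.upper(), start=1):
        if ch == "*":
            continue
        if ch not in _AA_INDEX and ch not in AMBIGUITY_CODES:
            raise ScoringError(f"non-amino-acid character {ch!r} at position {pos}")
        residues.append(ch)
        positions.append(pos)
    if not residues:
        raise ScoringError("sequence contains no scorable residues")
    return residues, positions


def _emission_lo(table: np.ndarray, node: int, residue: str) -> float:
    """Log2-odds emission of ``residue`` at 1-based ``node``; 0 for B/Z/X."""
    if residue in AMBIGUITY_CODES:
        return 0.0
    return float(table[node - 1, _AA_INDEX[residue]])


def _is_match_only(profile: ProfileHMM) -> bool:
    t = profile.transitions
    return bool(np.all(t[1:, _T_MI] == 0.0) and np.all(t[1:, _T_MD] == 0.0))


def _viterbi_match_only(
    profile: ProfileHMM, residues: list[str], positions: list[int]
) -> tuple[float, tuple[int, int] | None]:
    """Vectorized DP when insert/delete states are unreachable.

    Elementwise numpy ops reproduce the scalar accumulation order
    ``(prefix + transition) + emission`` bit-for-bit, which the
    brute-force oracle also uses.
    """
    mlo, _, tlog = profile.scoring_tables()
    M = profile.length
    tmm = tlog[1:M, _T_MM]  # transition M_j -> M_{j+1}, j = 1..M-1
    prev = np.full(M, _NEG_INF)
    start = np.zeros(M, dtype=np.int64)
    best = _NEG_INF
    best_span: tuple[int, int] | None = None
    amb_row = np.zeros(M)
    for i, ch in enumerate(residues, start=1):
        em = amb_row if ch in AMBIGUITY_CODES else mlo[:, _AA_INDEX[ch]]
        cont = prev[:-1] + tmm  # ending at j = 2..M, continued from j-1
        cur = em.copy()
        cur_start = np.full(M, i, dtype=np.int64)
        keep = cont >= 0.0
        cur[1:] = np.where(keep, cont + em[1:], em[1:])
        cur_start[1:] = np.where(keep, start[:-1], i)
        j = int(np.argmax(cur))
        if cur[j] > best:
            best = float(cur[j])
            best_span = (start_pos := int(cur_start[j]), i)
        prev, start = cur, cur_start
    if best_span is None or best == _NEG_INF:
        return _NEG_INF, None
    return best, (positions[best_span[0] - 1], positions[best_span[1] - 1])


def _viterbi_full(
    profile: ProfileHMM, residues: list[str], positions: list[int]
) -> tuple[float, tuple[int, int] | None]:
    mlo, ilo, tlog = profile.scoring_tables()
    M = profile.length
    L = len(residues)
    NEG = _NEG_INF
    # V*[j] for the current/previous number of consumed residues; 1-based j.
    vm_prev = [NEG] * (M + 1)
    vi_prev = [NEG] * (M + 1)
    vd_prev = [NEG] * (M + 1)
    sm_prev = [0] * (M + 1)
    si_prev = [0] * (M + 1)
    sd_prev = [0] * (M + 1)
    best = NEG
    best_span: tuple[int, int] | None = None
    for i in range(1, L + 1):
        ch = residues[i - 1]
        vm = [NEG] * (M + 1)
        vi = [NEG] * (M + 1)
        vd = [NEG] * (M + 1)
        sm = [0] * (M + 1)
        si = [0] * (M + 1)
        sd = [0] * (M + 1)
        for j in range(1, M + 1):
            em = _emission_lo(mlo, j, ch)
            # fresh zero-cost entry
            val, org = em, i
            if j > 1:
                for prev_v, prev_s, col in (
                    (vm_prev[j - 1], sm_prev[j - 1], _T_MM),
                    (vi_prev[j - 1], si_prev[j - 1], _T_IM),
                    (vd_prev[j - 1], sd_prev[j - 1], _T_DM),
                ):
                    cand = (prev_v + float(tlog[j - 1, col])) + em
                    if cand > val:
                        val, org = cand, prev_s
            vm[j], sm[j] = val, org
            # insert at node j (consumes the residue, stays at node j)
            iem = _emission_lo(ilo, j, ch)
            a = vm_prev[j] + float(tlog[j, _T_MI])
            b = vi_prev[j] + float(tlog[j, _T_II])
            if a >= b:
                vi[j], si[j] = a + iem, sm_prev[j]
            else:
                vi[j], si[j] = b + iem, si_prev[j]
            # delete at node j (consumes nothing; depends on same-i node j-1)
            if j > 1:
                a = vm[j - 1] + float(tlog[j - 1, _T_MD])
                b = vd[j - 1] + float(tlog[j - 1, _T_DD])
                if a >= b:
                    vd[j], sd[j] = a, sm[j - 1]
                else:
                    vd[j], sd[j] = b, sd[j - 1]
            if vm[j] > best:
                best = vm[j]
                best_span = (sm[j], i)
        vm_prev, vi_prev, vd_prev = vm, vi, vd
        sm_prev, si_prev, sd_prev = sm, si, sd
    if best_span is None or best == NEG:
        return NEG, None
    return best, (positions[best_span[0] - 1], positions[best_span[1] - 1])


def viterbi_score(
    profile: ProfileHMM, sequence: str
) -> tuple[float, tuple[int, int] | None]:
    """Best unihit local alignment score in bits, with its sequence span.

    Returns ``(-inf, None)`` when no finite-scoring path exists (every
    candidate alignment crosses a zero-probability emission).
    """
    residues, positions = _filter_sequence(sequence)
    if _is_match_only(profile):
        return _viterbi_match_only(profile, residues, positions)
    return _viterbi_full(profile, residues, positions)


def brute_force_score(
    profile: ProfileHMM, sequence: str, *, max_states: int = 4, max_len: int = 6
) -> float:
    """Exhaustive path-enumeration oracle for tiny models.

    Enumerates every legal state path under the same local-alignment
    convention as :func:`viterbi_score` and returns the maximum score.
    Exponential; refuses models larger than ``max_states`` x ``max_len``.
    """
    if profile.length > max_states:
        raise ScoringError(f"brute force limited to M <= {max_states}")
    residues, _ = _filter_sequence(sequence)
    if len(residues) > max_len:
        raise ScoringError(f"brute force limited to L <= {max_len}")
    mlo, ilo, tlog = profile.scoring_tables()
    M = profile.length
    L = len(residues)
    best = _NEG_INF

    def em(j: int, i: int) -> float:
        return _emission_lo(mlo, j, residues[i - 1])

    def iem(j: int, i: int) -> float:
        return _emission_lo(ilo, j, residues[i - 1])

    def walk(state: str, j: int, i: int, s: float) -> None:
        nonlocal best
        if state == "M":
            if s > best:
                best = s
            if j < M and i < L:
                walk("M", j + 1, i + 1, (s + float(tlog[j, _T_MM])) + em(j + 1, i + 1))
            if i < L:
                walk("I", j, i + 1, (s + float(tlog[j, _T_MI])) + iem(j, i + 1))
            if j < M:
                walk("D", j + 1, i, s + float(tlog[j, _T_MD]))
        elif state == "I":
            if i < L:
                walk("I", j, i + 1, (s + float(tlog[j, _T_II])) + iem(j, i + 1))
            if j < M and i < L:
                walk("M", j + 1, i + 1, (s + float(tlog[j, _T_IM])) + em(j + 1, i + 1))
        else:  # D
            if j < M:
                walk("D", j + 1, i, s + float(tlog[j, _T_DD]))
                if i < L:
                    walk("M", j + 1, i + 1, (s + float(tlog[j, _T_DM])) + em(j + 1, i + 1))

    for i0 in range(1, L + 1):
        for j0 in range(1, M + 1):
            walk("M", j0, i0, 0.0 + em(j0, i0))
    return best


# ---------------------------------------------------------------------------
# Hit calling
# ---------------------------------------------------------------------------

def effective_cutoff(
    profile: ProfileHMM,
    cutoffs: Mapping[str, float] | None,
    default_cutoff: float,
) -> float:
    """Cutoff table entry, else the model's GA line, else the default."""
    if cutoffs and profile.name in cutoffs:
        return float(cutoffs[profile.name])
    if profile.cutoff_bits is not None:
        return float(profile.cutoff_bits)
    return float(default_cutoff)


def call_hits(
    profiles: Sequence[ProfileHMM],
    proteome: Iterable[tuple[str, str]],
    cutoffs: Mapping[str, float] | None = None,
    default_cutoff: float = 40.0,
) -> list[HmmHit]:
    """Score every (sequence, profile) pair and call passes.

    A profile is considered present in the proteome iff at least one
    sequence passes its effective cutoff (see :func:`present_profiles`).
    """
    seqs = list(proteome)
    if not seqs:
        raise ScoringError("empty proteome")
    hits: list[HmmHit] = []
    for profile in profiles:
        cut = effective_cutoff(profile, cutoffs, default_cutoff)
        for seq_id, seq in seqs:
            score, span = viterbi_score(profile, seq)
            start, end = span if span is not None else (0, 0)
            hits.append(
                HmmHit(
                    sequence_id=seq_id,
                    profile_name=profile.name,
                    bit_score=score,
                    span_start=start,
                    span_end=end,
                    passed=bool(score >= cut),
                )
            )
    return hits


def present_profiles(hits: Iterable[HmmHit]) -> set[str]:
    return {h.profile_name for h in hits if h.passed}


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_cutoff_table(path: str | Path) -> dict[str, float]:
    """TSV with columns profile_name, bit_cutoff (header optional)."""
    table: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if lineno == 1 and fields[0] == "profile_name":
            continue
        if len(fields) < 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 columns")
        table[fields[0]] = float(fields[1])
    return table


def write_hits_tsv(hits: Sequence[HmmHit], path: str | Path) -> Path:
    """Hit table; scores rounded to 3 decimals for display only."""
    path = Path(path)
    lines = ["sequence_id\tprofile_name\tbit_score\tspan_start\tspan_end\tpassed"]
    for h in hits:
        score = "-inf" if h.bit_score == _NEG_INF else f"{h.bit_score:.3f}"
        lines.append(
            f"{h.sequence_id}\t{h.profile_name}\t{score}\t{h.span_start}\t{h.span_end}\t"
            f"{int(h.passed)}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
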