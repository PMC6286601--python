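"""Regular-expression motifs over the DNA alphabet and their search automata.

Motifs are written in a small regular-expression dialect over {A, C, G, T}
with ``N`` for any base, union ``|``, grouping ``(...)``, Kleene star ``*``
(the lazy form ``*?`` is accepted and treated identically) and the optional
quantifier ``?``.  ``U`` is transliterated to ``T`` so RNA-style patterns can
be used directly against DNA sequences.

A motif is compiled to a *search* automaton: a total deterministic finite
automaton (DFA) over the four bases that recognizes every position at which
an occurrence of the motif ends.  Scanning therefore never fails — there is
no dead state — and occurrences are registered as transitions into an end
state.  With the default overlapping counting mode the scan continues from
the end state, so overlapping occurrences are all counted; the
non-overlapping mode resets the automaton to its initial state after each
occurrence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ALPHABET",
    "RegexSyntaxError",
    "MotifTooComplexError",
    "Lit",
    "AnyBase",
    "Cat",
    "Alt",
    "Star",
    "Opt",
    "parse_regex",
    "render",
    "DFA",
    "build_dfa",
    "Motif",
    "encode_sequence",
    "count_occurrences",
    "count_occurrences_batch",
    "enumerate_matches",
    "enumerate_kmers",
    "combine_any",
    "combine_cooccur",
]

ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(ALPHABET)}

#: Default cap on the number of DFA states produced by subset construction.
#: Pathological expressions can blow up exponentially; we abort with a clear
#: error instead of exhausting memory.
DEFAULT_STATE_CAP = 100_000


class RegexSyntaxError(ValueError):
    """Raised for malformed motif patterns; carries the offending position."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


class MotifTooComplexError(ValueError):
    """Raised when an automaton would exceed the configured state cap."""


# ---------------------------------------------------------------------------
# Abstract syntax tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lit:
    """A single literal base (A, C, G or T)."""

    base: str


@dataclass(frozen=True)
class AnyBase:
    """The ``N`` wildcard: matches any of the four bases."""


@dataclass(frozen=True)
class Cat:
    """Concatenation of two or more sub-expressions (flattened)."""

    parts: tuple


@dataclass(frozen=True)
class Alt:
    """Union of two or more sub-expressions (flattened)."""

    parts: tuple


@dataclass(frozen=True)
class Star:
    """Kleene star: zero or more repetitions of the child."""

    child: object


@dataclass(frozen=True)
class Opt:
    """Optional group: zero or one occurrence of the child."""

    child: object


def _make_cat(parts: list) -> object:
    flat: list = []
    for p in parts:
        if isinstance(p, Cat):
            flat.extend(p.parts)
        else:
            flat.append(p)
    if len(flat) == 1:
        return flat[0]
    return Cat(tuple(flat))


def _make_alt(parts: list) -> object:
    flat: list = []
    for p in parts:
        if isinstance(p, Alt):
            flat.extend(p.parts)
        else:
            flat.append(p)
    if len(flat) == 1:
        return flat[0]
    return Alt(tuple(flat))


def parse_regex(pattern: str):
    """Parse a motif pattern into its abstract syntax tree.

    Lowercase input is accepted and ``U`` is transliterated to ``T``.  The
    resulting tree is canonical: unions and concatenations are flattened
    (treated associatively), so re-parsing a rendered tree reproduces a
    structurally identical tree.

    Raises
    ------
    RegexSyntaxError
        For unbalanced parentheses, dangling operators, empty groups or
        characters outside the ``{A,C,G,T,N,(,),|,*,?}`` alphabet, with the
        offending position in the message.
    """
    if not isinstance(pattern, str) or not pattern:
        raise RegexSyntaxError("empty pattern", 0)
    s = pattern.upper().replace("U", "T")
    n = len(s)
    depth_stack = []
    for i, ch in enumerate(s):
        if ch == "(":
            depth_stack.append(i)
        elif ch == ")":
            if not depth_stack:
                raise RegexSyntaxError("unbalanced parenthesis", i)
            depth_stack.pop()
    if depth_stack:
        raise RegexSyntaxError("unbalanced parenthesis", depth_stack[0])
    pos = 0

    def parse_alt():
        nonlocal pos
        parts = [parse_cat()]
        while pos < n and s[pos] == "|":
            pos += 1
            parts.append(parse_cat())
        return _make_alt(parts)

    def parse_cat():
        nonlocal pos
        factors = []
        while pos < n and s[pos] not in ")|":
            factors.append(parse_factor())
        if not factors:
            raise RegexSyntaxError("empty expression", pos)
        return _make_cat(factors)

    def parse_factor():
        nonlocal pos
        node = parse_atom()
        while pos < n and s[pos] in "*?":
            if s[pos] == "*":
                pos += 1
                # lazy star `*?` is equivalent to `*` here: occurrence
                # detection depends only on the recognized language
                if pos < n and s[pos] == "?":
                    pos += 1
                node = Star(node)
            else:
                pos += 1
                node = Opt(node)
        return node

    def parse_atom():
        nonlocal pos
        ch = s[pos]
        if ch in _CODE:
            pos += 1
            return Lit(ch)
        if ch == "N":
            pos += 1
            return AnyBase()
        if ch == "(":
            open_pos = pos
            pos += 1
            if pos < n and s[pos] == ")":
                raise RegexSyntaxError("empty group", pos)
            node = parse_alt()
            if pos >= n or s[pos] != ")":
                raise RegexSyntaxError("unbalanced parenthesis", open_pos)
            pos += 1
            return node
        if ch in "*?":
            raise RegexSyntaxError(f"dangling operator '{ch}'", pos)
        if ch == ")":
            raise RegexSyntaxError("unbalanced parenthesis", pos)
        raise RegexSyntaxError(f"invalid character {ch!r}", pos)

    ast = parse_alt()
    if pos != n:
        raise RegexSyntaxError("unbalanced parenthesis", pos)
    return ast


def render(ast) -> str:
    """Render an AST back to a pattern string (inverse of :func:`parse_regex`)."""
    if isinstance(ast, Lit):
        return ast.base
    if isinstance(ast, AnyBase):
        return "N"
    if isinstance(ast, Cat):
        out = []
        for p in ast.parts:
            r = render(p)
            out.append(f"({r})" if isinstance(p, Alt) else r)
        return "".join(out)
    if isinstance(ast, Alt):
        return "|".join(render(p) for p in ast.parts)
    if isinstance(ast, (Star, Opt)):
        r = render(ast.child)
        if not isinstance(ast.child, (Lit, AnyBase)):
            r = f"({r})"
        return r + ("*" if isinstance(ast, Star) else "?")
    raise TypeError(f"not an AST node: {ast!r}")


# ---------------------------------------------------------------------------
# Thompson NFA and subset construction
# ---------------------------------------------------------------------------

_ALL = frozenset(range(4))


class _NFA:
    """Thompson-style NFA with epsilon edges and base-set labelled edges."""

    def __init__(self):
        self.eps: list[list[int]] = []
        self.edges: list[list[tuple[frozenset, int]]] = []

    def new_state(self) -> int:
        self.eps.append([])
        self.edges.append([])
        return len(self.eps) - 1

    def add_eps(self, a: int, b: int) -> None:
        self.eps[a].append(b)

    def add_edge(self, a: int, syms: frozenset, b: int) -> None:
        self.edges[a].append((syms, b))


def _thompson(nfa: _NFA, ast) -> tuple[int, int]:
    """Compile *ast* into *nfa*; return its (start, accept) fragment states."""
    if isinstance(ast, Lit):
        a, b = nfa.new_state(), nfa.new_state()
        nfa.add_edge(a, frozenset({_CODE[ast.base]}), b)
        return a, b
    if isinstance(ast, AnyBase):
        a, b = nfa.new_state(), nfa.new_state()
        nfa.add_edge(a, _ALL, b)
        return a, b
    if isinstance(ast, Cat):
        start, acc = _thompson(nfa, ast.parts[0])
        for part in ast.parts[1:]:
            s2, a2 = _thompson(nfa, part)
            nfa.add_eps(acc, s2)
            acc = a2
        return start, acc
    if isinstance(ast, Alt):
        a, b = nfa.new_state(), nfa.new_state()
        for part in ast.parts:
            s2, a2 = _thompson(nfa, part)
            nfa.add_eps(a, s2)
            nfa.add_eps(a2, b)
        return a, b
    if isinstance(ast, Star):
        a, b = nfa.new_state(), nfa.new_state()
        s2, a2 = _thompson(nfa, ast.child)
        nfa.add_eps(a, s2)
        nfa.add_eps(a, b)
        nfa.add_eps(a2, s2)
        nfa.add_eps(a2, b)
        return a, b
    if isinstance(ast, Opt):
        a, b = nfa.new_state(), nfa.new_state()
        s2, a2 = _thompson(nfa, ast.child)
        nfa.add_eps(a, s2)
        nfa.add_eps(a, b)
        nfa.add_eps(a2, b)
        return a, b
    raise TypeError(f"not an AST node: {ast!r}")


def _closure(nfa: _NFA, states: Iterable[int]) -> frozenset:
    stack = list(states)
    seen = set(stack)
    while stack:
        s = stack.pop()
        for t in nfa.eps[s]:
            if t not in seen:
                seen.add(t)
                stack.append(t)
    return frozenset(seen)


@dataclass
class DFA:
    """Total deterministic automaton over {A, C, G, T}.

    ``delta`` is an ``(n_states, 4)`` integer array; ``is_end`` flags the
    states whose entry marks the end of a motif occurrence.  For search
    automata every state has four outgoing transitions and every state is
    reachable from ``start``; there is no dead state.
    """

    delta: np.ndarray
    is_end: np.ndarray
    start: int = 0

    @property
    def n_states(self) -> int:
        return self.delta.shape[0]

    @property
    def end_states(self) -> np.ndarray:
        return np.flatnonzero(self.is_end)

    def transition(self, state: int, base: str) -> int:
        return int(self.delta[state, _CODE[base]])


def _subset_construction(ast, search: bool, state_cap: int) -> tuple[DFA, bool]:
    """Build a DFA by Thompson + subset construction.

    With ``search=True`` the automaton recognizes ``.*pattern`` (total, no
    dead state).  With ``search=False`` it recognizes the pattern itself and
    may contain a dead state (used only for full-length match enumeration).
    Returns the DFA and a flag telling whether a dead state is present.
    """
    nfa = _NFA()
    p_start, p_acc = _thompson(nfa, ast)
    if search:
        root = nfa.new_state()
        nfa.add_edge(root, _ALL, root)
        nfa.add_eps(root, p_start)
        init = _closure(nfa, [root])
    else:
        init = _closure(nfa, [p_start])

    ids: dict[frozenset, int] = {init: 0}
    order = [init]
    rows: dict[int, list[int]] = {}
    queue = [init]
    while queue:
        subset = queue.pop()
        row = [0, 0, 0, 0]
        for sym in range(4):
            targets = set()
            for s in subset:
                for syms, t in nfa.edges[s]:
                    if sym in syms:
                        targets.add(t)
            nxt = _closure(nfa, targets)
            if nxt not in ids:
                ids[nxt] = len(order)
                order.append(nxt)
                queue.append(nxt)
                if len(order) > state_cap:
                    raise MotifTooComplexError(
                        f"automaton exceeds the state cap ({state_cap}); "
                        "the expression is likely pathological"
                    )
            row[sym] = ids[nxt]
        rows[ids[subset]] = row
    delta = np.zeros((len(order), 4), dtype=np.int32)
    for sid, row in rows.items():
        delta[sid] = row
    is_end = np.array([p_acc in subset for subset in order], dtype=bool)
    has_dead = any(len(subset) == 0 for subset in order)
    return DFA(delta=delta, is_end=is_end, start=0), has_dead


def _minimize(dfa: DFA) -> DFA:
    """Moore partition refinement preserving the end-state marking."""
    block = dfa.is_end.astype(np.int64)
    n_blocks = int(block.max()) + 1
    while True:
        sig = np.column_stack([block] + [block[dfa.delta[:, a]] for a in range(4)])
        _, new = np.unique(sig, axis=0, return_inverse=True)
        m = int(new.max()) + 1
        if m == n_blocks:
            break
        block, n_blocks = new, m
    # relabel so the start state's block is 0, preserving reachable order
    relabel = -np.ones(n_blocks, dtype=np.int64)
    relabel[block[dfa.start]] = 0
    nxt = 1
    for b in block:
        if relabel[b] < 0:
            relabel[b] = nxt
            nxt += 1
    block = relabel[block]
    delta = np.zeros((n_blocks, 4), dtype=np.int32)
    is_end = np.zeros(n_blocks, dtype=bool)
    for s in range(dfa.n_states):
        delta[block[s]] = block[dfa.delta[s]]
        is_end[block[s]] = dfa.is_end[s]
    return DFA(delta=delta, is_end=is_end, start=0)


def build_dfa(ast, minimize: bool = True, state_cap: int = DEFAULT_STATE_CAP) -> DFA:
    """Build the deterministic *search* automaton for an AST.

    The automaton accepts ``.*pattern``: entering an end state means an
    occurrence of the motif ends at the current position.  Subset
    construction aborts with :class:`MotifTooComplexError` beyond
    ``state_cap`` states; by default the result is Hopcroft/Moore-minimized
    (the end-state marking is preserved, so occurrence counting is
    unaffected).
    """
    dfa, _ = _subset_construction(ast, search=True, state_cap=state_cap)
    if minimize:
        dfa = _minimize(dfa)
    return dfa


# ---------------------------------------------------------------------------
# Motif container and counting
# ---------------------------------------------------------------------------

@dataclass
class Motif:
    """A compiled motif: pattern string, syntax tree and search automaton."""

    pattern: str
    ast: object
    dfa: DFA
    counting: str = "overlapping"
    state_cap: int = DEFAULT_STATE_CAP
    _match_dfa: object = field(default=None, repr=False)

    @classmethod
    def compile(
        cls,
        pattern: str,
        counting: str = "overlapping",
        minimize: bool = True,
        state_cap: int = DEFAULT_STATE_CAP,
    ) -> "Motif":
        if counting not in ("overlapping", "non-overlapping"):
            raise ValueError(f"unknown counting mode {counting!r}")
        ast = parse_regex(pattern)
        dfa = build_dfa(ast, minimize=minimize, state_cap=state_cap)
        return cls(pattern=pattern, ast=ast, dfa=dfa, counting=counting,
                   state_cap=state_cap)

    @property
    def match_dfa(self) -> DFA:
        """The full-match automaton (may include a dead state); built lazily."""
        if self._match_dfa is None:
            dfa, _ = _subset_construction(self.ast, search=False,
                                          state_cap=self.state_cap)
            self._match_dfa = dfa
        return self._match_dfa


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A=0 C=1 G=2 T=3, other=-1)."""
    table = np.full(256, -1, dtype=np.int8)
    for b, c in _CODE.items():
        table[ord(b)] = c
        table[ord(b.lower())] = c
    table[ord("U")] = _CODE["T"]
    table[ord("u")] = _CODE["T"]
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return table[arr]


def count_occurrences(motif: Motif, sequence: str, policy: str = "skip") -> int:
    """Count motif occurrences in a sequence by scanning its search DFA.

    Overlapping mode (default) increments the count at every symbol that
    moves the automaton into an end state and continues from that state;
    non-overlapping mode resets to the initial state after each occurrence.
    Symbols outside {A,C,G,T} are handled by *policy*: ``"skip"`` resets the
    automaton to its initial state (no match can span an unknown base).
    """
    if policy != "skip":
        raise ValueError(f"unknown non-ACGT policy {policy!r}")
    codes = encode_sequence(sequence)
    delta = motif.dfa.delta
    is_end = motif.dfa.is_end
    start = motif.dfa.start
    nonoverlap = motif.counting == "non-overlapping"
    state = start
    count = 0
    for code in codes:
        if code < 0:
            state = start
            continue
        state = int(delta[state, code])
        if is_end[state]:
            count += 1
            if nonoverlap:
                state = start
    return count


def count_occurrences_batch(motif: Motif, seq_matrix: np.ndarray) -> np.ndarray:
    """Vectorized occurrence counting over a batch of encoded sequences.

    ``seq_matrix`` is ``(n_sequences, max_length)`` int8 with ``-1`` for both
    padding and non-ACGT symbols (skip policy: automaton resets there).
    """
    delta = motif.dfa.delta
    is_end = motif.dfa.is_end
    start = motif.dfa.start
    nonoverlap = motif.counting == "non-overlapping"
    n, length = seq_matrix.shape
    states = np.full(n, start, dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    for pos in range(length):
        sym = seq_matrix[:, pos]
        valid = sym >= 0
        states = np.where(valid, delta[states, np.where(valid, sym, 0)], start)
        entered = valid & is_end[states]
        counts += entered
        if nonoverlap:
            states = np.where(entered, start, states)
    return counts


def enumerate_matches(motif: Motif, length: int, cap: int = 12) -> set[str]:
    """All length-*L* words over {A,C,G,T} the motif matches in full.

    A word qualifies when the whole word is an occurrence of the motif
    (an automaton path of exactly *L* symbols from the initial state to an
    end state of the full-match automaton).  The exhaustive output is capped
    at ``length <= cap`` words.
    """
    if length > cap:
        raise ValueError(f"length {length} exceeds the enumeration cap ({cap})")
    mdfa = motif.match_dfa
    # dead states: states from which no end state is reachable; prune them
    reach_end = _end_reachable(mdfa)
    out: set[str] = set()
    word = [""] * length

    def walk(state: int, depth: int) -> None:
        if depth == length:
            if mdfa.is_end[state]:
                out.add("".join(word))
            return
        for sym in range(4):
            nxt = int(mdfa.delta[state, sym])
            if reach_end[nxt]:
                word[depth] = ALPHABET[sym]
                walk(nxt, depth + 1)

    if reach_end[mdfa.start] or mdfa.is_end[mdfa.start]:
        walk(mdfa.start, 0)
    return out


def _end_reachable(dfa: DFA) -> np.ndarray:
    """Boolean mask of states from which some end state is reachable."""
    rev: list[list[int]] = [[] for _ in range(dfa.n_states)]
    for s in range(dfa.n_states):
        for sym in range(4):
            rev[int(dfa.delta[s, sym])].append(s)
    mask = dfa.is_end.copy()
    stack = list(np.flatnonzero(mask))
    while stack:
        s = stack.pop()
        for p in rev[s]:
            if not mask[p]:
                mask[p] = True
                stack.append(p)
    return mask


def enumerate_kmers(k: int) -> list[str]:
    """Lexicographic list of all 4^k DNA k-mers (1 <= k <= 10)."""
    if not 1 <= k <= 10:
        raise ValueError(f"k must be between 1 and 10, got {k}")
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


def combine_any(motifs: Sequence[str]) -> str:
    """Union pattern ``(m1)|(m2)|...`` matching any of the given motifs."""
    if not motifs:
        raise ValueError("need at least one pattern")
    return "|".join(f"({m})" for m in motifs)


def combine_cooccur(m1: str, m2: str) -> str:
    """Co-occurrence pattern ``(m1N*m2)|(m2N*m1)``: both motifs in either
    order with an arbitrary gap."""
    return f"({m1}N*{m2})|({m2}N*{m1})"
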