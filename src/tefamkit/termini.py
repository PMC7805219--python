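"""Terminal-sequence signatures for class II transposon classification.

Transposases recognize the outermost bases of their element, so transposons
with related transposases share similar termini even when the rest of the
sequence has diverged beyond recognition.  This module builds position
probability profiles from ungapped pile-ups of the first/last 60 bp of the
consensi in one classification category (5', 3', and a combined model for
TIR elements), scores new consensi against a signature library with
orientation and position filtering, detects target-site duplications, and
renders sequence logos.

Profiles are ungapped position probability tables; information content per
column is ``2 + sum_b p_b log2 p_b`` bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ParameterError, TefamkitError

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGTN", "TGCAN")

FIVE = "five_prime"
THREE = "three_prime"
COMBINED = "combined"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def extract_termini(consensus: str, L: int = 60) -> tuple[str, str]:
    """First and last ``L`` bases of a consensus, N-padded to fixed length.

    The 5' terminus is padded on the right, the 3' terminus on the left, so
    the element boundary always sits at the outer edge of the window.
    ``L`` is restricted to the 30-60 bp range in which terminal homologies
    are informative.
    """
    if not consensus:
        raise ParameterError("empty consensus")
    if not (30 <= L <= 60):
        raise ParameterError("terminus length must be in [30, 60]")
    seq = consensus.upper()
    m = min(L, len(seq))
    five = seq[:m] + "N" * (L - m)
    three = "N" * (L - m) + seq[-m:]
    return five, three


@dataclass
class TerminusPileup:
    """Ungapped fixed-length terminus rows for one category and end."""

    category: str
    end: str  # five_prime | three_prime | combined
    rows: list[str]
    source_family_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end not in (FIVE, THREE, COMBINED):
            raise ParameterError(f"unknown end {self.end!r}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ParameterError("pileup rows must share one length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class TerminiSignature:
    """Positional profiles for one class II category.

    ``profiles[end]`` is an (L, 4) pseudocounted probability table;
    ``information_content[end]`` the per-column IC in bits.
    ``tsd_expectation`` records the category's expected TSD length range and
    optional motif.
    """

    category: str
    profiles: dict[str, np.ndarray]
    information_content: dict[str, np.ndarray]
    tsd_expectation: tuple[int, int, Optional[str]] = (0, 0, None)
    n_families: int = 0

    def __post_init__(self) -> None:
        for end, p in self.profiles.items():
            if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
                raise ParameterError(f"{end} profile rows do not sum to 1")
            ic = self.information_content[end]
            if np.any(ic < -1e-9) or np.any(ic > 2 + 1e-9):
                raise ParameterError("information content outside [0, 2] bits")


@dataclass
class TerminiHit:
    """One scored signature match for a query consensus."""

    category: str
    end: str
    score: float
    offset: int
    orientation: str  # '+' or '-'


# ---------------------------------------------------------------------------
# Signature building
# ---------------------------------------------------------------------------

def _profile_from_rows(rows: list[str], pseudocount: float) -> tuple[np.ndarray, np.ndarray]:
    L = len(rows[0])
    counts = np.zeros((L, 4))
    for row in rows:
        for i, ch in enumerate(row.upper()):
            j = BASE_INDEX.get(ch)
            if j is not None:  # N excluded from counts
                counts[i, j] += 1
    probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        ic = 2.0 + np.sum(np.where(probs > 0, probs * np.log2(probs), 0.0), axis=1)
    return probs, np.clip(ic, 0.0, 2.0)


def _total_ic(rows: list[str], pseudocount: float) -> float:
    """Anchor-search objective: count-weighted empirical information.

    Each column contributes n * (2 + sum p log2 p) with p the observed
    (pseudocount-free) base frequencies over its n residues, so sliding a
    row away from the pile-up always costs information; a pseudocounted IC
    would be inflated by sparse columns.
    """
    L = len(rows[0])
    counts = np.zeros((L, 4))
    for row in rows:
        for i, ch in enumerate(row.upper()):
            j = BASE_INDEX.get(ch)
            if j is not None:
                counts[i, j] += 1
    n = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / np.maximum(n[:, None], 1)
        ent = np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
    return float(np.sum(n * (2.0 + ent)))


def _anchor_rows(rows: list[str], end: str, max_offset: int, pseudocount: float) -> list[str]:
    """Deterministic stand-in for by-hand pile-up alignment.

    Each row may slide 0..max_offset bases away from the terminus (N-filled
    on the vacated side); offsets are chosen greedily, two refinement passes,
    to maximize count-weighted column information.
    """
    if max_offset == 0 or len(rows) < 3:
        return list(rows)
    L = len(rows[0])

    def shifted(row: str, o: int) -> str:
        if o == 0:
            return row
        if end == THREE:  # anchor at the right edge: slide leftward, N-pad right
            return row[o:] + "N" * o
        return "N" * o + row[: L - o]  # 5'/combined: slide rightward

    current = list(rows)
    for _ in range(2):
        for i in range(len(current)):
            best_rows, best_ic = None, -np.inf
            for o in range(max_offset + 1):
                trial = current[:i] + [shifted(rows[i], o)] + current[i + 1 :]
                ic = _total_ic(trial, pseudocount)
                if ic > best_ic + 1e-12:
                    best_rows, best_ic = trial, ic
            current = best_rows
    return current


def build_signature(
    pileup_5: TerminusPileup,
    pileup_3: TerminusPileup,
    make_combined: bool = False,
    pseudocount: float = 0.5,
    anchor_offset: int = 3,
    tsd_expectation: tuple[int, int, Optional[str]] = (0, 0, None),
) -> TerminiSignature:
    """Build 5'/3' (and optionally combined) profiles for one category.

    The combined profile pools the 5' rows with the reverse-complemented 3'
    rows — for TIR elements both ends present the same transposase-binding
    signal.  Raises on singleton pile-ups (a one-row signature is
    unreliable).
    """
    if pileup_5.category != pileup_3.category:
        raise ParameterError("pileups belong to different categories")
    if len(pileup_5.rows) < 2 or len(pileup_3.rows) < 2:
        raise TefamkitError(
            f"category {pileup_5.category!r}: singleton pileup, signature "
            "would be unreliable"
        )
    rows5 = _anchor_rows(pileup_5.rows, FIVE, anchor_offset, pseudocount)
    rows3 = _anchor_rows(pileup_3.rows, THREE, anchor_offset, pseudocount)
    profiles: dict[str, np.ndarray] = {}
    ic: dict[str, np.ndarray] = {}
    profiles[FIVE], ic[FIVE] = _profile_from_rows(rows5, pseudocount)
    profiles[THREE], ic[THREE] = _profile_from_rows(rows3, pseudocount)
    if make_combined:
        pooled = rows5 + [revcomp(r) for r in rows3]
        pooled = _anchor_rows(pooled, COMBINED, anchor_offset, pseudocount)
        profiles[COMBINED], ic[COMBINED] = _profile_from_rows(pooled, pseudocount)
    return TerminiSignature(
        category=pileup_5.category,
        profiles=profiles,
        information_content=ic,
        tsd_expectation=tsd_expectation,
        n_families=len(pileup_5.rows),
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _score_placement(profile: np.ndarray, query: str, offset: int) -> float:
    """Sum of log2(p/0.25) over profile columns, query shifted by ``offset``.

    Positive offset slides the query toward higher profile columns; columns
    without a query residue (or with N) contribute 0 bits.
    """
    L = profile.shape[0]
    total = 0.0
    for col in range(L):
        qpos = col - offset
        if not (0 <= qpos < len(query)):
            continue
        j = BASE_INDEX.get(query[qpos])
        if j is None:
            continue
        total += float(np.log2(max(profile[col, j], 1e-12) / 0.25))
    return total


def _best_offset(profile: np.ndarray, query: str, slack: int) -> tuple[float, int]:
    best, best_o = -np.inf, 0
    for o in range(-slack, slack + 1):
        s = _score_placement(profile, query, o)
        if s > best:
            best, best_o = s, o
    return best, best_o


def classify_by_termini(
    query_consensus: str,
    library: list[TerminiSignature],
    slack: int = 3,
    min_bits: float = 8.0,
    L: int = 60,
) -> list[TerminiHit]:
    """Rank signature categories for a query consensus.

    The query's 5' and 3' termini are scored against every signature in both
    orientations (a reverse-orientation query presents its reverse-
    complemented 3' terminus to the 5' profile and vice versa), over placements
    within ``slack`` bp of the terminus.  A category is retained only when
    both ends match in a *consistent* orientation and each end exceeds
    ``min_bits`` — the orientation/position filter that makes these short
    homologies trustworthy.  Hits are ranked by combined score; an empty
    result is a valid "unclassified" outcome.
    """
    if not library:
        raise ParameterError("signature library is empty")
    q5, q3 = extract_termini(query_consensus, L)
    hits: list[TerminiHit] = []
    for sig in library:
        p5, p3 = sig.profiles[FIVE], sig.profiles[THREE]
        # forward: query 5' vs 5' profile, query 3' vs 3' profile
        f5, o5 = _best_offset(p5, q5, slack)
        f3, o3 = _best_offset(p3, q3, slack)
        # reverse strand: RC(3') presents as a 5' terminus and vice versa
        r5, ro5 = _best_offset(p5, revcomp(q3), slack)
        r3, ro3 = _best_offset(p3, revcomp(q5), slack)
        candidates = []
        if f5 > min_bits and f3 > min_bits:
            candidates.append(("+", f5 + f3, o5, o3))
        if r5 > min_bits and r3 > min_bits:
            candidates.append(("-", r5 + r3, ro5, ro3))
        if not candidates:
            continue
        orient, combined, off5, off3 = max(candidates, key=lambda c: c[1])
        hits.append(TerminiHit(category=sig.category, end=COMBINED,
                               score=combined, offset=off5, orientation=orient))
    hits.sort(key=lambda h: (-h.score, h.category))
    return hits


# ---------------------------------------------------------------------------
# Serialization (stored standalone or inside a family store)
# ---------------------------------------------------------------------------

def signature_to_dict(sig: TerminiSignature) -> dict:
    return {
        "category": sig.category,
        "profiles": {end: p.tolist() for end, p in sig.profiles.items()},
        "information_content": {
            end: ic.tolist() for end, ic in sig.information_content.items()
        },
        "tsd_expectation": list(sig.tsd_expectation),
        "n_families": sig.n_families,
    }


def signature_from_dict(d: dict) -> TerminiSignature:
    return TerminiSignature(
        category=d["category"],
        profiles={end: np.array(p) for end, p in d["profiles"].items()},
        information_content={
            end: np.array(ic) for end, ic in d["information_content"].items()
        },
        tsd_expectation=tuple(d.get("tsd_expectation", (0, 0, None))),
        n_families=d.get("n_families", 0),
    )


# ---------------------------------------------------------------------------
# Target site duplications
# ---------------------------------------------------------------------------

def detect_tsd(
    flank_left: str,
    flank_right: str,
    k_range: tuple[int, int] = (2, 20),
) -> Optional[tuple[int, str]]:
    """Longest direct repeat across an insertion: last k of the left flank ==
    first k of the right flank.

    One mismatch is tolerated for k >= 8.  Returns ``(length, motif)`` using
    the left-flank copy, or None when no k >= max(2, k_range[0]) matches.
    Flanks must be at least 20 bp.
    """
    if len(flank_left) < 20 or len(flank_right) < 20:
        raise ParameterError("flanks must be at least 20 bp")
    lo, hi = k_range
    lo = max(lo, 2)
    left = flank_left.upper()
    right = flank_right.upper()
    for k in range(min(hi, len(left), len(right)), lo - 1, -1):
        a = left[-k:]
        b = right[:k]
        mismatches = sum(1 for x, y in zip(a, b) if x != y or x == "N")
        allowed = 1 if k >= 8 else 0
        if mismatches <= allowed:
            return k, a
    return None


def solo_ltr_features(consensus: str, tsd_len: Optional[int] = None) -> dict[str, bool]:
    """Structural solo-LTR diagnostics: TG...CA termini, poly-A signal, 4-6 bp TSD."""
    seq = consensus.upper()
    return {
        "tg_start": seq.startswith("TG"),
        "ca_end": seq.endswith("CA"),
        "polya_signal": "AATAAA" in seq,
        "tsd_4_6": tsd_len is not None and 4 <= tsd_len <= 6,
    }


def looks_like_solo_ltr(consensus: str, tsd_len: Optional[int] = None) -> bool:
    feats = solo_ltr_features(consensus, tsd_len)
    structural = feats["tg_start"] and feats["ca_end"] and feats["polya_signal"]
    return structural and (tsd_len is None or feats["tsd_4_6"])


# ---------------------------------------------------------------------------
# Logos
# ---------------------------------------------------------------------------

_LOGO_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}


def render_logo(sig: TerminiSignature, end: str, path) -> Path:
    """Render a sequence logo SVG: letter stack heights = p_b * IC(column)."""
    if end not in sig.profiles:
        raise ParameterError(f"signature has no {end!r} profile")
    probs = sig.profiles[end]
    ic = sig.information_content[end]
    L = probs.shape[0]
    col_w, unit_h, pad = 14, 40, 6  # unit_h pixels per bit, 2-bit axis
    width = L * col_w + 2 * pad
    height = 2 * unit_h + 2 * pad
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        f'<rect width="{width}" height="{height}" fill="white"/>',
    ]
    for col in range(L):
        order = np.argsort(probs[col])  # smallest drawn first (bottom)
        y = height - pad
        letters = []
        for j in order:
            h = float(probs[col, j] * ic[col]) * unit_h
            if h < 0.1:
                continue
            base = BASES[j]
            x = pad + col * col_w + col_w / 2
            # scale a unit glyph (16 px tall) vertically to the stack height
            letters.append(
                f'<g transform="translate({x:.1f},{y:.1f}) scale(1,{h / 16:.4f})">'
                f'<text x="0" y="0" text-anchor="middle" font-family="monospace" '
                f'font-size="16" fill="{_LOGO_COLORS[base]}">{base}</text></g>'
            )
            y -= h
        parts.append(f'<g class="logo-col">{"".join(letters)}</g>')
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts))
    return Path(path)
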