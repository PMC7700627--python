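"""Conserved-motif discovery by ZOOPS expectation-maximization.

A MEME-style search: each candidate motif is a position weight matrix
fit under the ZOOPS model (zero or one occurrence per sequence) against
a 0-order background, by EM from several random-subsequence starts.
Motifs are discovered sequentially — the best motif (by information
content per column) is reported, its sites masked, and the search
repeated up to a maximum count or until signal falls below an
information-content floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import SequenceRecord

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
MASK = "X"  # neutral symbol excluded from counting
PSEUDOCOUNT = 0.01
# Ambiguity letters occasionally seen in published consensus strings;
# treated as matching any residue when comparing consensi.
AMBIGUOUS = set("BZJX")


@dataclass
class Motif:
    """A discovered position weight model."""

    index: int                      # 1-based discovery order
    width: int
    pwm: np.ndarray                 # (width, 20), rows sum to 1
    consensus: str
    sites: list[tuple[str, int]]    # (sequence_id, 1-based start)
    annotation: str = ""
    loglik: float = float("nan")
    ic_total: float = float("nan")  # bits, relative to background
    low_confidence: bool = False
    objective_history: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.width < 2:
            raise ValueError("motif width must be >= 2")
        if self.pwm.shape != (self.width, len(ALPHABET)):
            raise ValueError("pwm shape must be (width, 20)")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every pwm position must sum to 1")
        if len(self.consensus) != self.width:
            raise ValueError("consensus length must equal width")

    @property
    def ic_per_column(self) -> float:
        return self.ic_total / self.width


def consensus_distance(a: str, b: str) -> int:
    """Hamming distance between consensi; ambiguity letters match anything."""
    if len(a) != len(b):
        raise ValueError("consensi must have equal length")
    return sum(
        1 for x, y in zip(a, b)
        if x != y and x not in AMBIGUOUS and y not in AMBIGUOUS
    )


def _encode(seqs) -> tuple[list[str], list[np.ndarray]]:
    ids, arrs = [], []
    for i, s in enumerate(seqs):
        sid = s.id if isinstance(s, SequenceRecord) else f"seq{i + 1}"
        res = s.residues if isinstance(s, SequenceRecord) else str(s)
        ids.append(sid)
        arrs.append(np.array([AA_INDEX.get(a, -1) for a in res], dtype=np.int64))
    return ids, arrs


def _background(arrs) -> np.ndarray:
    counts = np.full(len(ALPHABET), PSEUDOCOUNT)
    for a in arrs:
        v = a[a >= 0]
        counts += np.bincount(v, minlength=len(ALPHABET))
    return counts / counts.sum()


def _windows(arr: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    """All length-`width` windows and a validity mask (no masked residue)."""
    n = len(arr) - width + 1
    if n <= 0:
        return np.empty((0, width), dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(arr, width)
    return win, (win >= 0).all(axis=1)


def em_zoops(seqs, width: int, n_starts: int = 10, seed: int = 0,
             max_iter: int = 200, tol: float = 1e-4,
             _background_freqs: np.ndarray | None = None) -> Motif:
    """Fit one motif of the given width under the ZOOPS model.

    EM is restarted from ``n_starts`` random length-``width``
    subsequences; the start with the highest final log-likelihood wins.
    Iteration stops when the objective gains less than ``tol`` or after
    ``max_iter`` rounds. ``objective_history`` on the returned Motif is
    the EM objective (log-likelihood plus the Dirichlet-pseudocount
    prior term), which is non-decreasing by the EM guarantee.
    """
    if width < 2:
        raise ValueError("motif width must be >= 2")
    if not seqs:
        raise ValueError("em_zoops requires at least one sequence")
    ids, arrs = _encode(seqs)
    for sid, a in zip(ids, arrs):
        if len(a) < width:
            raise ValueError(
                f"sequence {sid!r} (length {len(a)}) is shorter than motif "
                f"width {width}"
            )
    bg = _background(arrs) if _background_freqs is None else _background_freqs
    wins, valids = zip(*(_windows(a, width) for a in arrs))
    usable = [i for i in range(len(arrs)) if valids[i].any()]
    if not usable:
        raise ValueError("no sequence has an unmasked window of this width")
    rng = np.random.default_rng(seed)

    # constant background log-likelihood of all (unmasked) residues
    const = sum(np.log(bg[a[a >= 0]]).sum() for a in arrs)
    logbg = np.log(bg)

    def run_em(theta, gamma):
        history = []
        prev_obj = -np.inf
        z_list = []
        loglik = const
        for _ in range(max_iter):
            logtheta = np.log(theta)
            z_list, q_sum, loglik = [], 0.0, const
            for i in usable:
                w, ok = wins[i], valids[i]
                # log odds of a site at each valid start
                lo = (logtheta[np.arange(width)[None, :], w[ok]]
                      - logbg[w[ok]]).sum(axis=1)
                m = ok.sum()
                odds = np.exp(lo - lo.max())
                # L_i = (1-gamma) + (gamma/m) * sum(exp(lo))
                s = odds.sum()
                lmax = lo.max()
                li = (1 - gamma) * np.exp(-lmax) + (gamma / m) * s
                loglik += lmax + np.log(li)
                z = (gamma / m) * odds / li  # site posterior per valid start
                z_list.append((i, z))
                q_sum += z.sum()
            # objective = loglik + Dirichlet prior on theta
            obj = loglik + PSEUDOCOUNT * np.log(theta).sum()
            history.append(obj)
            if obj - prev_obj < tol and np.isfinite(prev_obj):
                break
            prev_obj = obj
            # M-step
            counts = np.full((width, len(ALPHABET)), PSEUDOCOUNT)
            for i, z in z_list:
                w = wins[i][valids[i]]
                for k in range(width):
                    np.add.at(counts[k], w[:, k], z)
            theta = counts / counts.sum(axis=1, keepdims=True)
            gamma = min(max(q_sum / len(usable), 1e-6), 1 - 1e-6)
        # site assignment: zero-or-one per sequence, posterior > 0.5
        sites = []
        raw_sites = []
        for i, z in z_list:
            if z.sum() > 0.5:
                j = np.flatnonzero(valids[i])[int(np.argmax(z))]
                sites.append((ids[i], int(j) + 1))
                raw_sites.append((i, int(j)))
        return loglik, theta, gamma, sites, raw_sites, history

    def theta_from_sites(raw_sites, delta):
        counts = np.full((width, len(ALPHABET)), PSEUDOCOUNT)
        n_used = 0
        for i, j in raw_sites:
            js = j + delta
            if 0 <= js < len(valids[i]) and valids[i][js]:
                counts[np.arange(width), wins[i][js]] += 1.0
                n_used += 1
        if n_used == 0:
            return None
        return counts / counts.sum(axis=1, keepdims=True)

    best = None
    for _ in range(n_starts):
        i0 = usable[rng.integers(len(usable))]
        j0 = np.flatnonzero(valids[i0])[rng.integers(valids[i0].sum())]
        theta0 = np.full((width, len(ALPHABET)), 0.5 / (len(ALPHABET) - 1))
        theta0[np.arange(width), wins[i0][j0]] = 0.5
        cand = run_em(theta0, 0.5)
        if best is None or cand[0] > best[0]:
            best = cand

    # phase refinement: restart EM from the converged sites shifted by a few
    # columns either way; repeated until a full sweep stops improving, so
    # the run can walk out of off-by-one (and off-by-two) local optima
    for _ in range(6):
        anchor = best
        for delta in (-2, -1, 1, 2):
            theta0 = theta_from_sites(anchor[4], delta)
            if theta0 is None:
                continue
            cand = run_em(theta0, anchor[2])
            if cand[0] > best[0]:
                best = cand
        if best is anchor:
            break

    loglik, theta, _, sites, _, history = best
    ic = float((theta * (np.log2(theta) - np.log2(bg))).sum())
    consensus = "".join(ALPHABET[k] for k in theta.argmax(axis=1))
    return Motif(
        index=1, width=width, pwm=theta, consensus=consensus, sites=sites,
        loglik=float(loglik), ic_total=ic, low_confidence=ic / width < 1.0,
        objective_history=[float(x) for x in history],
    )


def discover_motifs(seqs, max_motifs: int = 10,
                    widths: tuple[int, ...] = (28, 41, 50),
                    seed: int = 0, n_starts: int = 10,
                    ic_floor: float = 8.0) -> list[Motif]:
    """Sequential motif discovery with site masking.

    Each round fits one motif per candidate width on the currently
    masked sequences, keeps the best by information content per column,
    masks its sites with a neutral symbol excluded from all counts, and
    repeats. Discovery stops at ``max_motifs``, when the best motif's
    total information content falls below ``ic_floor`` bits, when fewer
    than two sequences retain an unmasked window, or when a motif is
    supported by fewer than two sites.
    """
    if max_motifs < 1:
        raise ValueError("max_motifs must be >= 1")
    ids, arrs = _encode(seqs)
    if not ids:
        raise ValueError("discover_motifs requires input sequences")
    working = [list(s.residues if isinstance(s, SequenceRecord) else str(s))
               for s in seqs]
    rng = np.random.default_rng(seed)
    motifs: list[Motif] = []
    for round_no in range(1, max_motifs + 1):
        masked = [SequenceRecord(i, "".join(w), "protein")
                  for i, w in zip(ids, working)]
        candidates = []
        for width in widths:
            ok = [i for i, w in enumerate(working)
                  if _windows(np.array([AA_INDEX.get(a, -1) for a in w]),
                              width)[1].any()]
            if len(ok) < 2:
                continue
            sub = [masked[i] for i in ok]
            if min(len(s.residues) for s in sub) < width:
                continue
            try:
                m = em_zoops(sub, width, n_starts=n_starts,
                             seed=int(rng.integers(2 ** 31)))
            except ValueError:
                continue
            candidates.append(m)
        if not candidates:
            break
        best = max(candidates, key=lambda m: m.ic_per_column)
        if best.ic_total < ic_floor or len(best.sites) < 2:
            break
        best.index = round_no
        motifs.append(best)
        for sid, start in best.sites:
            w = working[ids.index(sid)]
            for k in range(start - 1, start - 1 + best.width):
                w[k] = MASK
    return motifs
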