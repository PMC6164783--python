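"""MEME-style ungapped motif discovery by ZOOPS expectation-maximization.

Each motif is a fixed-width PWM fit under the zero-or-one-occurrence-per-
sequence model: EM alternates posterior site responsibilities with PWM and
site-probability updates, the best of several seeded restarts is kept, and
the winning sites are hard-masked before the next motif is sought.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .kinase_scan import AA, AA_INDEX

PSEUDOCOUNT = 0.01


@dataclass
class MotifModel:
    width: int
    pwm: np.ndarray  # width x 20 probabilities
    sites: list[tuple[str, int]]  # (seq id, 0-based offset)
    information_content: float
    loglik_trajectory: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def consensus(self) -> str:
        return "".join(AA[i] for i in self.pwm.argmax(axis=1))

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        return np.log2(self.pwm / background[None, :])


def _encode(seqs: dict[str, str]) -> dict[str, np.ndarray]:
    return {sid: np.array([AA_INDEX[a] for a in s]) for sid, s in seqs.items()}


def _background(encoded: dict[str, np.ndarray]) -> np.ndarray:
    counts = np.full(20, 1.0)  # +1 smoothing
    for x in encoded.values():
        counts += np.bincount(x, minlength=20)
    return counts / counts.sum()


def _available_windows(x: np.ndarray, mask: np.ndarray, width: int):
    """(window index matrix, offsets) of windows free of masked positions."""
    if len(x) < width:
        return np.empty((0, width), dtype=int), np.empty(0, dtype=int)
    wins = sliding_window_view(x, width)
    free = sliding_window_view(mask, width).all(axis=1)
    offs = np.nonzero(free)[0]
    return wins[free], offs


def _em_single(windows: dict[str, np.ndarray], bg: np.ndarray, width: int,
               init_pwm: np.ndarray, max_iter: int = 200,
               tol: float = 1e-4):
    """Fit one ZOOPS motif by EM; returns (pwm, gamma, loglik trajectory)."""
    pwm = init_pwm.copy()
    gamma = 0.5
    log_bg = np.log(bg)
    trajectory: list[float] = []
    cols = np.arange(width)
    for _ in range(max_iter):
        total_counts = np.full((width, 20), PSEUDOCOUNT)
        q_sum, n_seqs, ll = 0.0, 0, 0.0
        log_pwm = np.log(pwm)
        posteriors = {}
        for sid, wins in windows.items():
            if wins.shape[0] == 0:
                continue
            n_seqs += 1
            m = wins.shape[0]
            log_ratio = (log_pwm[cols, wins] - log_bg[wins]).sum(axis=1)
            # stabilized mixture: no-site vs site-at-j
            a = np.log(max(1 - gamma, 1e-300))
            b = np.log(max(gamma, 1e-300)) - np.log(m) + log_ratio
            mx = max(a, b.max())
            denom = np.exp(a - mx) + np.exp(b - mx).sum()
            ll += mx + np.log(denom)
            z = np.exp(b - mx) / denom
            posteriors[sid] = z
            q_sum += z.sum()
            np.add.at(total_counts, (cols[None, :], wins),
                      z[:, None] * np.ones((1, width)))
        gamma = min(max(q_sum / max(n_seqs, 1), 1e-6), 1 - 1e-6)
        pwm = total_counts / total_counts.sum(axis=1, keepdims=True)
        trajectory.append(ll)
        if len(trajectory) > 1 and abs(trajectory[-1] - trajectory[-2]) < tol:
            break
    return pwm, gamma, trajectory, posteriors


def _rank_seed_windows(windows, bg, width, seed_pool, rng, n_keep,
                       max_candidates: int = 300):
    """Pick promising EM starting windows by cross-sequence support.

    Each candidate window is turned into a sharp PWM and scored by the sum
    over sequences of the best window log-odds; windows whose pattern recurs
    across sequences score highest, which steers EM toward the correct
    register rather than a shifted one.
    """
    if len(seed_pool) > max_candidates:
        pick = rng.choice(len(seed_pool), size=max_candidates, replace=False)
        candidates = [seed_pool[i] for i in sorted(pick)]
    else:
        candidates = seed_pool
    log_bg = np.log(bg)
    scored = []
    log_match, log_miss = np.log(0.5), np.log(0.5 / 19)
    cols = np.arange(width)
    for sid, k in candidates:
        seed_win = windows[sid][k]
        total = 0.0
        for wins in windows.values():
            if wins.shape[0] == 0:
                continue
            matches = (wins == seed_win[None, :])
            log_ratio = (np.where(matches, log_match, log_miss)
                         - log_bg[wins]).sum(axis=1)
            total += log_ratio.max()
        scored.append((total, sid, k))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [(sid, k) for _, sid, k in scored[:n_keep]]


def em_motif_search(seqs: dict[str, str], width: int = 15,
                    n_motifs: int = 20, restarts: int = 5,
                    seed: int = 0) -> list[MotifModel]:
    """Discover up to n_motifs ungapped motifs with hard erasing.

    Deterministic under seed. Motifs are returned sorted by information
    content (relative entropy to the 0-order background), descending.
    """
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    shortest = min(len(s) for s in seqs.values())
    if width > shortest:
        raise ValueError(f"width {width} exceeds shortest sequence "
                         f"({shortest})")
    encoded = _encode(seqs)
    bg = _background(encoded)
    masks = {sid: np.ones(len(x), dtype=bool) for sid, x in encoded.items()}
    rng = np.random.default_rng(seed)
    motifs: list[MotifModel] = []
    for _ in range(n_motifs):
        windows, offsets = {}, {}
        seed_pool = []
        for sid, x in encoded.items():
            w, o = _available_windows(x, masks[sid], width)
            windows[sid], offsets[sid] = w, o
            seed_pool.extend((sid, k) for k in range(len(o)))
        if not seed_pool:
            break
        starts = _rank_seed_windows(windows, bg, width, seed_pool, rng,
                                    n_keep=restarts)
        best = None
        for sid, k in starts:
            init = np.full((width, 20), 0.5 / 19)
            init[np.arange(width), windows[sid][k]] = 0.5
            fit = _em_single(windows, bg, width, init)
            if best is None or fit[2][-1] > best[2][-1]:
                best = fit
        pwm, gamma, trajectory, posteriors = best
        sites = []
        for sid in sorted(posteriors):
            z = posteriors[sid]
            j = int(z.argmax())
            if z[j] > 0.5:
                sites.append((sid, int(offsets[sid][j])))
        for sid, off in sites:
            masks[sid][off:off + width] = False
        ic = float((pwm * np.log2(pwm / bg[None, :])).sum())
        motifs.append(MotifModel(width=width, pwm=pwm, sites=sites,
                                 information_content=ic,
                                 loglik_trajectory=trajectory))
    motifs.sort(key=lambda m: -m.information_content)
    return motifs


def motif_architecture(proteins: dict[str, str], motifs: list[MotifModel],
                       score_threshold: float = 5.0,
                       groups: dict[str, str] | None = None,
                       shared_fraction: float = 1.0):
    """Presence/order matrix of motifs across proteins + per-group shared set.

    A motif is present in a protein when its best window log-odds score (vs
    the motif set's background) reaches score_threshold. Returns
    (presence: dict id -> list of (motif index, offset) in N->C order,
    shared: dict group -> set of motif indices).
    """
    if not proteins:
        return {}, {}
    encoded = _encode(proteins)
    bg = _background(encoded)
    presence: dict[str, list[tuple[int, int]]] = {}
    for sid, x in encoded.items():
        hits = []
        for mi, motif in enumerate(motifs):
            if len(x) < motif.width:
                continue
            lo = motif.log_odds(bg)
            wins = sliding_window_view(x, motif.width)
            scores = lo[np.arange(motif.width), wins].sum(axis=1)
            j = int(scores.argmax())
            if scores[j] >= score_threshold:
                hits.append((mi, j))
        hits.sort(key=lambda t: t[1])
        presence[sid] = hits
    shared: dict[str, set[int]] = {}
    if groups:
        for g in sorted(set(groups.values())):
            members = [sid for sid in proteins if groups.get(sid) == g]
            if not members:
                continue
            shared[g] = {mi for mi in range(len(motifs))
                         if sum(1 for sid in members
                                if mi in {h[0] for h in presence[sid]})
                         >= shared_fraction * len(members)}
    return presence, shared


def write_meme_minimal(motifs: list[MotifModel], background: np.ndarray,
                       path) -> None:
    """Serialize motifs in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + AA + "\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{a} {background[i]:.5f}"
                          for i, a in enumerate(AA)) + "\n\n")
        for k, m in enumerate(motifs, start=1):
            fh.write(f"MOTIF motif_{k} {m.consensus}\n")
            fh.write(f"letter-probability matrix: alength= 20 w= {m.width} "
                     f"nsites= {len(m.sites)}\n")
            for row in m.pwm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
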