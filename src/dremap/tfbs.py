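"""PWM scanning and motif gain/loss statistics at associated substitutions.

Scanning is a log-odds scan of both strands; a window is a hit when its
score's tail probability under the background base composition is at most
``p_threshold``. The score distribution is computed exactly by dynamic-
programming convolution over a discretized score grid, so the threshold
is deterministic.

For an associated SNP the CLL-enriched allele is treated as mutant (MU)
and the other allele as wild type (WT). Per motif t, aggregated over the
SNPs of a region class:

    Fract(lost|t)   = N(t|WT, not MU) / N(t|WT)
    Fract(gained|t) = N(t|MU, not WT) / N(t|MU)

where hits are counted only in the window overlapping the substituted
base. Significance is the strict upper-tail binomial probability with
trial count N(t|WT) (lost) or N(t|MU) (gained) and success probability
p_t, the same fraction measured at background positions carrying the WT
base elsewhere in the host region.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import interval_overlap_bp

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_PERM = np.array([3, 2, 1, 0])  # A<->T, C<->G
GRANULARITY = 1000


def encode(seq: str) -> np.ndarray:
    """Map a sequence to 0..3 codes; anything else (N) becomes 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def reverse_complement(seq: str) -> str:
    table = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(table)[::-1]


@dataclass
class Pwm:
    """Position weight matrix with a calibrated log-odds hit threshold."""

    motif_id: str
    probs: np.ndarray  # shape (width, 4), rows sum to 1, column order ACGT
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (width, 4)")
        if self.width < 4:
            raise ValueError("motif width must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        adj = (self.probs + self.pseudocount) / (1 + 4 * self.pseudocount)
        self.log_odds = np.log2(adj / self.background)
        # discretize for the exact DP score distribution
        shifted = self.log_odds - self.log_odds.min(axis=1, keepdims=True)
        span = shifted.max(axis=1).sum()
        self._scale = GRANULARITY / span if span > 0 else 1.0
        self.int_scores = np.rint(shifted * self._scale).astype(np.int64)
        self._threshold_cache: dict[float, int] = {}

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def score_distribution(self) -> np.ndarray:
        """Exact pmf of the discretized window score under the background."""
        pmf = np.array([1.0])
        for i in range(self.width):
            width_here = self.int_scores[i].max()
            new = np.zeros(len(pmf) + width_here)
            for j in range(4):
                s = self.int_scores[i, j]
                new[s : s + len(pmf)] += self.background[j] * pmf
            pmf = new
        return pmf

    def int_threshold(self, p_threshold: float) -> int:
        """Smallest discretized score whose background tail is <= p_threshold."""
        if p_threshold in self._threshold_cache:
            return self._threshold_cache[p_threshold]
        pmf = self.score_distribution()
        sf = np.cumsum(pmf[::-1])[::-1]
        above = np.nonzero(sf <= p_threshold)[0]
        thr = int(above[0]) if len(above) else len(pmf)
        self._threshold_cache[p_threshold] = thr
        return thr

    def reverse_complement_ints(self) -> np.ndarray:
        return self.int_scores[::-1, _COMPLEMENT_PERM]

    def window_score(self, codes: np.ndarray) -> float:
        """Real log-odds score of one encoded window (no N)."""
        return float(self.log_odds[np.arange(self.width), codes].sum())


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int
    strand: str
    motif_id: str
    score: float


def _scan_ints(codes: np.ndarray, ints: np.ndarray, threshold: int) -> np.ndarray:
    """Offsets of windows scoring >= threshold; windows containing N skipped."""
    w = ints.shape[0]
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return np.array([], dtype=int)
    scores = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    padded = np.vstack([ints.T, np.zeros((1, w), dtype=np.int64)])  # row 4 = N
    for k in range(w):
        window_codes = codes[k : k + n_win]
        scores += padded[window_codes, k]
        valid &= window_codes != 4
    return np.nonzero(valid & (scores >= threshold))[0]


def scan_sequence(pwm: Pwm, sequence: str, p_threshold: float = 1e-4,
                  sequence_id: str = "seq") -> list[MotifHit]:
    """All hits of the motif on both strands of the sequence.

    A minus-strand hit at offset o covers the same forward window
    [o, o + width); its score is that of the reverse-complement window.
    """
    codes = encode(sequence)
    if len(codes) < pwm.width:
        return []
    threshold = pwm.int_threshold(p_threshold)
    hits: list[MotifHit] = []
    for strand, ints in (("+", pwm.int_scores), ("-", pwm.reverse_complement_ints())):
        for off in _scan_ints(codes, ints, threshold):
            window = codes[off : off + pwm.width]
            if strand == "-":
                window = _COMPLEMENT_PERM[window[::-1]]
            hits.append(MotifHit(sequence_id, int(off), strand, pwm.motif_id,
                                 pwm.window_score(window)))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def sample_matched_controls(region_seq: str, region_repeat_fraction: float,
                            genome: dict[str, str],
                            repeat_index: dict[str, tuple[np.ndarray, np.ndarray]],
                            n: int = 10, gc_tol: float = 0.05,
                            repeat_tol: float = 0.05, seed: int = 0,
                            max_attempts: int | None = None) -> list[str]:
    """Random genome windows matching the region's length, GC content and
    repeat density within the given tolerances (rejection sampling).

    Returns fewer than n sequences with a warning when the attempt budget
    is exhausted.
    """
    length = len(region_seq)
    target_gc = gc_content(region_seq)
    chroms = [c for c, s in genome.items() if len(s) >= length]
    if not chroms:
        raise ValueError("no chromosome long enough for control sampling")
    weights = np.array([len(genome[c]) - length + 1 for c in chroms], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    budget = max_attempts if max_attempts is not None else 500 * n
    controls: list[str] = []
    for _ in range(budget):
        if len(controls) == n:
            break
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        start = int(rng.integers(0, len(genome[chrom]) - length + 1))
        window = genome[chrom][start : start + length]
        if "N" in window.upper():
            continue
        if abs(gc_content(window) - target_gc) > gc_tol:
            continue
        rep = interval_overlap_bp(chrom, start, start + length, repeat_index) / length
        if abs(rep - region_repeat_fraction) > repeat_tol:
            continue
        controls.append(window)
    if len(controls) < n:
        warnings.warn(
            f"control sampling budget exhausted: {len(controls)}/{n} controls found")
    return controls


def gc_content(seq: str) -> float:
    s = seq.upper()
    acgt = sum(s.count(b) for b in BASES)
    if acgt == 0:
        return float("nan")
    return (s.count("G") + s.count("C")) / acgt


def tfbs_enrichment(region_seqs: list[str], control_seqs: list[str],
                    pwms: list[Pwm], p_threshold: float = 1e-4) -> pd.DataFrame:
    """Per-motif hit density (hits/kb) ratio of regions over controls."""
    region_kb = sum(len(s) for s in region_seqs) / 1000
    control_kb = sum(len(s) for s in control_seqs) / 1000
    rows = []
    for pwm in pwms:
        n_region = sum(len(scan_sequence(pwm, s, p_threshold)) for s in region_seqs)
        n_control = sum(len(scan_sequence(pwm, s, p_threshold)) for s in control_seqs)
        d_region = n_region / region_kb if region_kb else float("nan")
        d_control = n_control / control_kb if control_kb else float("nan")
        if d_control == 0:
            ratio = float("inf") if d_region > 0 else float("nan")
        else:
            ratio = d_region / d_control
        rows.append((pwm.motif_id, n_region, n_control, d_region, d_control, ratio))
    return pd.DataFrame(rows, columns=[
        "motif_id", "region_hits", "control_hits",
        "region_density_per_kb", "control_density_per_kb", "density_ratio"])


@dataclass
class SnpContext:
    """An associated SNP embedded in its host region sequence.

    ``offset`` indexes the substituted base within ``sequence``; the
    sequence carries the WT allele at that offset.
    """

    snp_id: str
    sequence: str
    offset: int
    wt_allele: str
    mu_allele: str

    def __post_init__(self) -> None:
        base = self.sequence[self.offset].upper()
        if base != self.wt_allele.upper():
            raise ValueError(
                f"{self.snp_id}: sequence base {base} != WT allele {self.wt_allele}")

    def mutant_sequence(self) -> str:
        s = self.sequence
        return s[: self.offset] + self.mu_allele + s[self.offset + 1 :]


def sample_background_positions(context: SnpContext, n: int = 30,
                                seed: int = 0) -> list[SnpContext]:
    """Background pseudo-substitutions: positions in the host sequence
    carrying the WT base (excluding the SNP itself), each assigned the MU
    allele. Fewer than n candidates → all are used."""
    seq = context.sequence.upper()
    wt = context.wt_allele.upper()
    candidates = [i for i, b in enumerate(seq) if b == wt and i != context.offset]
    if not candidates:
        logger.warning("%s: no background positions with WT base", context.snp_id)
        return []
    rng = np.random.default_rng(seed)
    if len(candidates) > n:
        chosen = sorted(rng.choice(len(candidates), size=n, replace=False))
        candidates = [candidates[i] for i in chosen]
    return [
        SnpContext(f"{context.snp_id}_bg{i}", context.sequence, pos,
                   context.wt_allele, context.mu_allele)
        for i, pos in enumerate(candidates)
    ]


@dataclass
class TfbsChangeStats:
    motif_id: str
    direction: str
    n_ref: int          # N(t|WT) for lost, N(t|MU) for gained
    n_changed: int      # N(t|WT, not MU) for lost, N(t|MU, not WT) for gained
    fraction: float
    p_t: float          # background fraction
    p_value: float      # strict upper-tail binomial
    enrichment: float   # fraction / p_t


def _allele_hit_sets(context: SnpContext, pwm: Pwm, p_threshold: float) -> tuple[set, set]:
    """Hit keys (offset, strand) overlapping the substituted base, for the
    WT and MU alleles. Only the window of width 2w-1 around the SNP is
    scanned: every motif-width subwindow of it overlaps the SNP."""
    w = pwm.width
    lo = max(0, context.offset - (w - 1))
    hi = min(len(context.sequence), context.offset + w)
    wt_win = context.sequence[lo:hi]
    mu_win = context.mutant_sequence()[lo:hi]
    wt_hits = {(lo + h.offset, h.strand) for h in scan_sequence(pwm, wt_win, p_threshold)}
    mu_hits = {(lo + h.offset, h.strand) for h in scan_sequence(pwm, mu_win, p_threshold)}
    return wt_hits, mu_hits


def _change_counts(contexts: list[SnpContext], pwm: Pwm,
                   p_threshold: float) -> tuple[int, int, int, int]:
    n_wt = n_wt_not_mu = n_mu = n_mu_not_wt = 0
    for ctx in contexts:
        wt_hits, mu_hits = _allele_hit_sets(ctx, pwm, p_threshold)
        n_wt += len(wt_hits)
        n_wt_not_mu += len(wt_hits - mu_hits)
        n_mu += len(mu_hits)
        n_mu_not_wt += len(mu_hits - wt_hits)
    return n_wt, n_wt_not_mu, n_mu, n_mu_not_wt


def motif_change_stats(contexts: list[SnpContext], pwms: list[Pwm],
                       direction: str, background_contexts: list[SnpContext],
                       p_threshold: float = 1e-4) -> list[TfbsChangeStats]:
    """Aggregated motif gain/loss statistics over a class's SNPs.

    direction "lost": fraction of WT hits destroyed by the MU allele;
    "gained": fraction of MU hits absent under WT. Motifs with a zero
    denominator are skipped with a log note.
    """
    if direction not in ("lost", "gained"):
        raise ValueError("direction must be 'lost' or 'gained'")
    out: list[TfbsChangeStats] = []
    for pwm in pwms:
        n_wt, n_wt_not_mu, n_mu, n_mu_not_wt = _change_counts(contexts, pwm, p_threshold)
        b_wt, b_wt_not_mu, b_mu, b_mu_not_wt = _change_counts(
            background_contexts, pwm, p_threshold)
        if direction == "lost":
            n_ref, n_changed = n_wt, n_wt_not_mu
            b_ref, b_changed = b_wt, b_wt_not_mu
        else:
            n_ref, n_changed = n_mu, n_mu_not_wt
            b_ref, b_changed = b_mu, b_mu_not_wt
        if n_ref == 0:
            logger.info("motif %s: no %s-denominator hits; skipped", pwm.motif_id, direction)
            continue
        fraction = n_changed / n_ref
        p_t = b_changed / b_ref if b_ref else float("nan")
        if np.isnan(p_t):
            p_value = float("nan")
            enrichment = float("nan")
        else:
            p_value = float(stats.binom.sf(n_changed, n_ref, p_t))
            enrichment = fraction / p_t if p_t > 0 else (
                float("inf") if fraction > 0 else float("nan"))
        out.append(TfbsChangeStats(pwm.motif_id, direction, n_ref, n_changed,
                                   fraction, p_t, p_value, enrichment))
    return out


def write_meme(pwms: list[Pwm], path) -> None:
    """Minimal MEME motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                     f"nsites= 20 E= 0\n")
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[Pwm]:
    """Read a minimal MEME motif file (as written by :func:`write_meme`)."""
    pwms: list[Pwm] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    for line in lines:
        if line.startswith("Background letter frequencies"):
            vals = next(lines).split()
            background = np.array([float(vals[i]) for i in (1, 3, 5, 7)])
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            header = next(lines)
            width = int(header.split("w=")[1].split()[0])
            rows = [np.array(next(lines).split(), dtype=float) for _ in range(width)]
            pwms.append(Pwm(motif_id, np.vstack(rows), background=background.copy()))
    return pwms
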