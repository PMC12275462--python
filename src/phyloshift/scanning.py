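"""Scanning orchestration at three resolutions.

* element scan — score each BED region: ML rate-shift fit, LRT,
  permulation calibration with adaptive pruning, leave-one-out
  robustness;
* window scan — tile the reference with sliding windows and score each
  as an element, producing a bedGraph convergence track (optionally
  parametric-only: the uncalibrated signed LRT score is emitted);
* motif scan — locate PWM hits on the reference sequence and score each
  hit's alignment slice, plus a global per-motif enrichment test
  (one-sided hypergeometric, BH-corrected across motifs).

Per-element seeds derive only from the global seed and the element's
identity, so results are independent of region order and worker count.
"""
from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .calibration import (
    CalibrationConfig,
    adaptive_calibrate,
    leave_one_out_robustness,
)
from .io import MafBlock, Region, ScoreRecord
from .likelihood import Alignment, LikelihoodEngine, foreground_branches
from .permulation import PermulationConfig, PermulationError, null_trait_stream
from .rate_shift import fit_alt, fit_null, lrt
from .substitution import ALPHABET, NeutralModel

__all__ = [
    "Pwm",
    "MotifHit",
    "EnrichmentRecord",
    "ScanConfig",
    "score_alignment",
    "score_elements",
    "score_windows",
    "pwm_scan",
    "read_pwms",
    "motif_global_enrichment",
    "fasta_extractor",
    "maf_extractor",
]

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Knobs shared by all scan resolutions."""

    alpha: float = 0.05
    n_permulations: int = 1000
    seed: int = 0
    min_species: int = 0         # minimum rows with any non-missing data
    calibrate: bool = True
    leave_one_out: bool = True
    match_clades: bool = True
    loo_p_threshold: float = 0.05


def element_seed(global_seed: int, label: str) -> int:
    """Stable per-element sub-seed from the element's identity."""
    h = zlib.crc32(label.encode())
    ss = np.random.SeedSequence([global_seed, h])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Element scoring


def score_alignment(
    alignment: Alignment,
    model: NeutralModel,
    fg_tips: Sequence[str],
    region: Region,
    config: ScanConfig,
) -> ScoreRecord:
    """Run the full pipeline on one extracted alignment."""
    tree = model.tree
    fg = foreground_branches(tree, fg_tips)
    engine = LikelihoodEngine(alignment, model)
    null = fit_null(engine)
    alt = fit_alt(engine, None, fg, null)
    res = lrt(null, alt)
    rec = ScoreRecord(
        region=region,
        rho0=null.rho0,
        rho1=alt.rho1,
        lambda_hat=alt.lam,
        lrt_p=res.pvalue,
    )
    if not config.calibrate:
        # parametric-only mode: the scorr column carries the uncalibrated
        # signed LRT score
        rec.scorr = res.signed_score
        return rec

    def scorer(tips: frozenset[str]) -> float:
        spec = foreground_branches(tree, tips)
        a = fit_alt(engine, None, spec, null)
        return lrt(null, a).signed_score

    seed = element_seed(config.seed, region.label)
    perm_cfg = PermulationConfig(
        n_max=config.n_permulations,
        match_clades=config.match_clades,
        seed=seed,
    )
    calib_cfg = CalibrationConfig(
        alpha=config.alpha,
        n_max=config.n_permulations,
        loo_p_threshold=config.loo_p_threshold,
        seed=seed,
    )
    stream = null_trait_stream(tree, fg, perm_cfg)
    conv = adaptive_calibrate(scorer, fg, stream, calib_cfg, alt.lam)
    rec.pcorr = conv.pcorr
    rec.scorr = conv.scorr
    rec.n_permulations_used = len(conv.null_set)
    if config.leave_one_out:
        rec.robust, _ = leave_one_out_robustness(
            engine, None, fg,
            loo_p_threshold=config.loo_p_threshold,
            null=null, full_alt=alt,
        )
    return rec


def score_elements(
    extractor: Callable[[Region], Alignment | None],
    regions: Sequence[Region],
    model: NeutralModel,
    fg_tips: Sequence[str],
    config: ScanConfig | None = None,
) -> list[ScoreRecord]:
    """Score every region; failures yield reason-coded NA records.

    Output row count always equals the input region count.
    """
    config = config or ScanConfig()
    records: list[ScoreRecord] = []
    for region in regions:
        try:
            aln = extractor(region)
        except Exception as exc:  # extraction must never kill the run
            logger.warning("%s: extraction failed: %s", region.label, exc)
            records.append(ScoreRecord(region, reason="extraction_error"))
            continue
        if aln is None or aln.length == 0:
            logger.warning("%s: no aligned columns", region.label)
            records.append(ScoreRecord(region, reason="no_alignment"))
            continue
        if aln.n_informative_species() < config.min_species:
            logger.warning("%s: insufficient species", region.label)
            records.append(ScoreRecord(region, reason="insufficient_species"))
            continue
        try:
            records.append(score_alignment(aln, model, fg_tips, region, config))
        except PermulationError as exc:
            logger.warning("%s: %s", region.label, exc)
            records.append(ScoreRecord(region, reason="permulation_failed"))
        logger.info("scored %s", region.label)
    return records


def fasta_extractor(alignment: Alignment) -> Callable[[Region], Alignment | None]:
    """Treat a FASTA alignment as one reference-coordinate contig:
    region start/end index its columns directly."""

    def extract(region: Region) -> Alignment | None:
        if region.start >= alignment.length:
            return None
        return alignment.slice_columns(region.start, min(region.end, alignment.length))

    return extract


def maf_extractor(source: str | Path | Iterable[MafBlock]):
    """Region extractor over MAF blocks (loaded once, stream-sliced)."""
    from .io import extract_region, read_maf

    blocks = list(read_maf(source)) if isinstance(source, (str, Path)) else list(source)

    def extract(region: Region) -> Alignment | None:
        return extract_region(blocks, region)

    return extract


# ---------------------------------------------------------------------------
# Window scan (convergence track)


def tile_windows(
    chrom: str, start: int, end: int, window: int, step: int
) -> list[Region]:
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    return [
        Region(chrom, s, min(s + window, end), f"win_{chrom}_{s}")
        for s in range(start, end, step)
        if s < end
    ]


def score_windows(
    maf_source: str | Path | Iterable[MafBlock],
    window: int,
    step: int,
    model: NeutralModel,
    fg_tips: Sequence[str],
    config: ScanConfig | None = None,
) -> list[ScoreRecord]:
    """Tile the reference coverage of a MAF and score each window."""
    from .io import read_maf

    config = config or ScanConfig()
    blocks = (
        list(read_maf(maf_source))
        if isinstance(maf_source, (str, Path))
        else list(maf_source)
    )
    spans: dict[str, tuple[int, int]] = {}
    for b in blocks:
        lo, hi = spans.get(b.ref_chrom, (b.ref_start, b.ref_end))
        spans[b.ref_chrom] = (min(lo, b.ref_start), max(hi, b.ref_end))
    regions: list[Region] = []
    for chrom in sorted(spans):
        lo, hi = spans[chrom]
        regions.extend(tile_windows(chrom, lo, hi, window, step))
    return score_elements(maf_extractor(blocks), regions, model, fg_tips, config)


# ---------------------------------------------------------------------------
# PWM scanning


@dataclass
class Pwm:
    """Position weight matrix as log2-odds against a background."""

    motif_id: str
    matrix: np.ndarray  # (length, 4) log-odds

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM must be at least 4 positions long")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("PWM contains non-finite entries")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.01,
    ) -> "Pwm":
        counts = np.asarray(counts, dtype=np.float64)
        bg = (
            np.full(4, 0.25)
            if background is None
            else np.asarray(background, dtype=np.float64)
        )
        freq = (counts + pseudocount * bg) / (
            counts.sum(axis=1, keepdims=True) + pseudocount
        )
        return cls(motif_id, np.log2(freq / bg))

    def reverse_complement(self) -> np.ndarray:
        return self.matrix[::-1, ::-1]


@dataclass(frozen=True)
class MotifHit:
    region: Region  # carries the strand
    motif_id: str
    pwm_score: float


def read_pwms(
    source: str | Path,
    background: np.ndarray | None = None,
    pseudocount: float = 0.01,
) -> list[Pwm]:
    """Read count/frequency matrices (HOCOMOCO-style four-column text,
    one or more '>'-headed records per file or per directory)."""
    from Bio import motifs as bio_motifs

    paths: list[Path]
    src = Path(source)
    paths = sorted(src.glob("*")) if src.is_dir() else [src]
    out: list[Pwm] = []
    for path in paths:
        with open(path) as handle:
            for m in bio_motifs.parse(handle, "pfm-four-columns"):
                counts = np.array(
                    [[m.counts[b][i] for b in ALPHABET] for i in range(m.length)]
                )
                motif_id = m.name or path.stem
                out.append(Pwm.from_counts(motif_id, counts, background, pseudocount))
    if not out:
        raise ValueError(f"no PWM records found in {source}")
    return out


def pwm_scan(
    sequence: str,
    pwms: Sequence[Pwm],
    threshold_frac: float = 0.8,
    *,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """Slide each PWM over both strands of the reference sequence.

    A hit requires score >= threshold_frac * max achievable score for
    that PWM; windows containing N are skipped.  Overlapping hits of the
    same motif are resolved greedily to the best score (ties: leftmost,
    then + strand).
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    seq = sequence.upper()
    code = np.full(len(seq), 4, dtype=np.int8)
    for i, c in enumerate(seq):
        if c in ALPHABET:
            code[i] = ALPHABET.index(c)
    hits: list[MotifHit] = []
    for pwm in pwms:
        L = pwm.length
        if L > len(seq):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(code, L)  # (n,L)
        valid = (windows != 4).all(axis=1)
        threshold = threshold_frac * pwm.max_score
        candidates: list[tuple[float, int, int]] = []  # (score, start, strand_rank)
        for strand_rank, mat in enumerate([pwm.matrix, pwm.reverse_complement()]):
            safe = np.where(windows == 4, 0, windows)
            scores = np.take_along_axis(
                mat[None, :, :], safe[:, :, None], axis=2
            )[:, :, 0].sum(axis=1)
            for start in np.nonzero(valid & (scores >= threshold))[0]:
                candidates.append((float(scores[start]), int(start), strand_rank))
        # greedy best-score resolution of overlaps within this motif
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        taken: list[tuple[int, int]] = []
        for score, start, strand_rank in candidates:
            end = start + L
            if any(start < t_end and end > t_start for t_start, t_end in taken):
                continue
            taken.append((start, end))
            strand = "+" if strand_rank == 0 else "-"
            hits.append(
                MotifHit(
                    Region(chrom, offset + start, offset + end,
                           f"{pwm.motif_id}|{chrom}:{offset + start}", strand),
                    pwm.motif_id,
                    score,
                )
            )
    hits.sort(key=lambda h: (h.region.chrom, h.region.start, h.motif_id))
    return hits


# ---------------------------------------------------------------------------
# Global motif enrichment


@dataclass
class EnrichmentRecord:
    motif_id: str
    n_sig_with_motif: int
    n_sig_without: int
    n_nonsig_with: int
    n_nonsig_without: int
    odds_ratio: float
    p: float
    fdr_q: float
    significant: bool


def motif_global_enrichment(
    scored_hits: Sequence[tuple[str, ScoreRecord]],
    direction: str,
    *,
    p_threshold: float = 0.05,
    require_robust: bool = True,
    fdr: float = 0.05,
) -> list[EnrichmentRecord]:
    """Per-motif one-sided enrichment of significant hits vs all others.

    A hit counts as significant when pcorr <= p_threshold, the shift
    direction matches (accelerated: scorr < 0; decelerated: scorr > 0),
    and — unless disabled — the leave-one-out robustness flag is set.
    Fisher's exact test (hypergeometric, one-sided 'greater') per motif,
    Benjamini–Hochberg across motifs.
    """
    if direction not in {"accel", "decel"}:
        raise ValueError("direction must be 'accel' or 'decel'")

    def is_sig(rec: ScoreRecord) -> bool:
        if rec.pcorr is None or rec.scorr is None or rec.pcorr > p_threshold:
            return False
        if require_robust and rec.robust is not True:
            return False
        return rec.scorr < 0 if direction == "accel" else rec.scorr > 0

    motifs = sorted({m for m, _ in scored_hits})
    total_sig = sum(is_sig(r) for _, r in scored_hits)
    total = len(scored_hits)
    rows: list[tuple[str, int, int, int, int]] = []
    for motif in motifs:
        with_motif = [r for m, r in scored_hits if m == motif]
        if not with_motif:
            continue
        a = sum(is_sig(r) for r in with_motif)
        b = total_sig - a
        c = len(with_motif) - a
        d = (total - total_sig) - c
        rows.append((motif, a, b, c, d))
    pvals = []
    ors = []
    for _, a, b, c, d in rows:
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        ors.append(float(odds) if math.isfinite(odds) else float("inf"))
        pvals.append(float(p))
    qvals = (
        stats.false_discovery_control(pvals, method="bh") if pvals else np.array([])
    )
    return [
        EnrichmentRecord(motif, a, b, c, d, orat, p, float(q), bool(q <= fdr))
        for (motif, a, b, c, d), orat, p, q in zip(rows, ors, pvals, qvals)
    ]
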