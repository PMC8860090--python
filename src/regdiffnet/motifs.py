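"""Motif-prior construction: PWM scanning of promoter windows under an exact
score-distribution null, and IUPAC consensus scanning.

A position weight matrix (PWM) gives, per motif position, a probability for
each base. A promoter window (default 750 bp upstream through 250 bp
downstream of the transcription start site) is scanned on both strands; a
window is a hit when the upper-tail p-value of its log-odds score under a
0-order background null is at or below the threshold (default 1e-4). The
binary TF x gene motif prior marks a 1 wherever a TF has at least one hit in
a gene's promoter.

Coordinates: internally positions are signed offsets with the TSS base at 0.
Reported coordinates are 1-based TSS-relative with no position 0 (the TSS
base is +1, the base before it is -1), so spans such as -311..+75 (386 bp)
are arithmetically exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

ETV2_CONSENSUS = "CCGGAW"


class MotifError(ValueError):
    """Malformed motif input or an impossible scoring request."""


class MemeParseError(MotifError):
    """MEME-minimal parse failure; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def report_coord(offset: int) -> int:
    """Map an internal TSS-at-0 offset to the 1-based no-zero convention."""
    return offset if offset < 0 else offset + 1


def internal_coord(reported: int) -> int:
    """Inverse of :func:`report_coord`."""
    if reported == 0:
        raise ValueError("position 0 does not exist in reported coordinates")
    return reported if reported < 0 else reported - 1


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (N, gaps) -> -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class PositionWeightMatrix:
    """Per-position base probabilities for one TF binding motif."""

    motif_id: str
    tf_name: str
    probs: np.ndarray  # L x 4, columns A C G T
    pseudocount: float = 1e-4

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise MotifError(f"motif {self.motif_id}: probs must be L x 4")
        if self.probs.shape[0] < 1:
            raise MotifError(f"motif {self.motif_id}: empty matrix")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise MotifError(f"motif {self.motif_id}: rows must sum to 1")
        self.probs = self.probs / sums[:, None]

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def smoothed_probs(self) -> np.ndarray:
        """Probabilities after the additive pseudocount, renormalized."""
        p = self.probs + self.pseudocount
        return p / p.sum(axis=1, keepdims=True)

    def reverse_complement(self) -> "PositionWeightMatrix":
        return replace(self, probs=self.probs[::-1, ::-1].copy())


@dataclass(frozen=True)
class MotifScanConfig:
    p_threshold: float = 1e-4
    window_upstream: int = 750
    window_downstream: int = 250
    both_strands: bool = True
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    score_granularity: float = 1e-3  # bin width as a fraction of score range

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise MotifError("p_threshold must lie in (0, 1)")
        if self.window_upstream < 0 or self.window_downstream < 0:
            raise MotifError("window lengths must be non-negative")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise MotifError("background probabilities must sum to 1")


@dataclass
class Promoter:
    """One promoter sequence anchored to its gene's TSS.

    ``start`` is the internal offset of the first base (TSS base = 0), so an
    unclipped default window has start = -750. Minus-strand genes are stored
    already reverse-complemented: position +1 is downstream of the TSS in the
    direction of transcription.
    """

    gene_id: str
    sequence: str
    start: int = -750
    strand: str = "+"
    clipped_upstream: bool = False
    clipped_downstream: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    tf: str
    gene: str
    offset: int  # reported (no-zero) TSS-relative coordinate of match start
    strand: str
    score: float
    p_value: float


# ---------------------------------------------------------------------------
# MEME-minimal I/O


def read_meme(path) -> list[PositionWeightMatrix]:
    """Parse a MEME-minimal motif file (alphabet order A, C, G, T)."""
    motifs: list[PositionWeightMatrix] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line.startswith("MOTIF"):
            i += 1
            continue
        parts = line.split()
        if len(parts) < 2:
            raise MemeParseError("MOTIF line without an identifier", i + 1)
        motif_id = parts[1]
        tf_name = parts[2] if len(parts) > 2 else motif_id
        i += 1
        while i < n and "letter-probability matrix" not in lines[i]:
            if lines[i].strip().startswith("MOTIF"):
                raise MemeParseError(
                    f"motif {motif_id}: missing letter-probability matrix", i + 1
                )
            i += 1
        if i >= n:
            raise MemeParseError(
                f"motif {motif_id}: missing letter-probability matrix", n
            )
        header = lines[i]
        m = re.search(r"w=\s*(\d+)", header)
        width = int(m.group(1)) if m else None
        i += 1
        rows = []
        while i < n:
            stripped = lines[i].strip()
            if not stripped or stripped.startswith(("MOTIF", "URL")):
                break
            fields = stripped.split()
            try:
                row = [float(x) for x in fields]
            except ValueError:
                raise MemeParseError(
                    f"motif {motif_id}: non-numeric matrix entry", i + 1
                ) from None
            if len(row) != 4:
                raise MemeParseError(
                    f"motif {motif_id}: expected 4 columns, got {len(row)}", i + 1
                )
            rows.append(row)
            i += 1
        if width is not None and len(rows) != width:
            raise MemeParseError(
                f"motif {motif_id}: matrix truncated ({len(rows)} of {width} rows)",
                i,
            )
        if not rows:
            raise MemeParseError(f"motif {motif_id}: empty matrix", i)
        motifs.append(PositionWeightMatrix(motif_id, tf_name, np.array(rows)))
    return motifs


def write_meme(motifs: list[PositionWeightMatrix], path,
               background=(0.25, 0.25, 0.25, 0.25)) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {0:.5f} C {1:.5f} G {2:.5f} T {3:.5f}\n\n".format(*background))
        for pwm in motifs:
            fh.write(f"MOTIF {pwm.motif_id} {pwm.tf_name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{p:.10f}" for p in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# promoter extraction


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def extract_promoters(
    genome: dict[str, str],
    tss_table: pd.DataFrame,
    window_upstream: int = 750,
    window_downstream: int = 250,
) -> list[Promoter]:
    """Cut TSS-anchored windows out of a genome.

    ``tss_table`` columns: gene, chrom, tss (0-based position of the TSS
    base), strand. The plus-strand window is the 0-based half-open interval
    [tss - upstream, tss + downstream + 1); minus-strand genes take the
    mirrored window [tss - downstream, tss + upstream + 1) and are
    reverse-complemented so the returned sequence reads in transcription
    direction. Windows are clipped at chromosome ends with the clip recorded.
    """
    missing = [
        str(row.gene)
        for row in tss_table.itertuples()
        if str(row.chrom) not in genome
    ]
    if missing:
        raise MotifError(
            "chromosome missing from FASTA for genes: " + ", ".join(missing)
        )
    promoters = []
    for row in tss_table.itertuples():
        chrom_seq = genome[str(row.chrom)]
        tss = int(row.tss)
        strand = str(row.strand)
        if strand == "+":
            lo, hi = tss - window_upstream, tss + window_downstream + 1
        else:
            lo, hi = tss - window_downstream, tss + window_upstream + 1
        clip_lo = max(lo, 0)
        clip_hi = min(hi, len(chrom_seq))
        seq = chrom_seq[clip_lo:clip_hi]
        if strand == "+":
            start = -window_upstream + (clip_lo - lo)
            clipped_up = clip_lo > lo
            clipped_down = clip_hi < hi
        else:
            seq = reverse_complement(seq)
            start = -window_upstream + (hi - clip_hi)
            clipped_up = clip_hi < hi
            clipped_down = clip_lo > lo
        promoters.append(
            Promoter(
                gene_id=str(row.gene),
                sequence=seq,
                start=start,
                strand=strand,
                clipped_upstream=clipped_up,
                clipped_downstream=clipped_down,
            )
        )
    return promoters


# ---------------------------------------------------------------------------
# exact score null


class ScoreDistribution:
    """Exact null distribution of a PWM's log-odds score.

    Scores are log2((p + pseudocount, renormalized) / background), discretized
    to bins of width ``granularity`` x (attainable finite score range). The
    distribution of the L-position sum under i.i.d. background positions is
    computed by dynamic programming (convolution over positions); bases with
    probability 0 (pseudocount 0) score -infinity and their probability mass
    is tracked separately so the finite tail is exact.
    """

    def __init__(self, pwm: PositionWeightMatrix, background=None,
                 granularity: float = 1e-3):
        bg = np.asarray(
            background if background is not None else (0.25,) * 4, dtype=float
        )
        if abs(bg.sum() - 1.0) > 1e-9 or (bg < 0).any():
            raise MotifError("background must be a probability vector")
        p = pwm.smoothed_probs()
        if ((bg == 0) & (p > 0)).any():
            raise MotifError(
                f"motif {pwm.motif_id}: zero background probability for a base "
                "with positive motif probability gives an infinite score"
            )
        with np.errstate(divide="ignore"):
            scores = np.log2(np.where(p > 0, p, np.nan) / np.where(bg > 0, bg, np.nan))
        scores = np.where(p > 0, scores, -np.inf)  # pseudocount-0 zeros
        self.scores = scores  # L x 4, may contain -inf
        self.background = bg
        finite = np.isfinite(scores)
        if not finite.any(axis=1).all():
            raise MotifError(
                f"motif {pwm.motif_id}: a position has no scoreable base"
            )
        smax = np.where(finite, scores, -np.inf).max(axis=1).sum()
        smin = np.where(finite, scores, np.inf).min(axis=1).sum()
        span = smax - smin
        self.delta = granularity * span if span > 0 else 1.0
        # integer bin per (position, base); -inf kept as is
        with np.errstate(invalid="ignore"):
            self.bins = np.where(
                finite, np.round(scores / self.delta), -np.inf
            )
        self._build_null()

    def _build_null(self):
        L = self.bins.shape[0]
        pmf = np.array([1.0])
        offset = 0  # integer score of pmf[0]
        for i in range(L):
            finite_mask = np.isfinite(self.bins[i])
            ks = self.bins[i, finite_mask].astype(int)
            ps = self.background[finite_mask]
            lo, hi = ks.min(), ks.max()
            kernel = np.zeros(hi - lo + 1)
            for k, pr in zip(ks, ps):
                kernel[k - lo] += pr
            pmf = np.convolve(pmf, kernel)
            offset += lo
        self.pmf = pmf
        self.offset = offset
        self.neg_inf_mass = 1.0 - pmf.sum()
        # suffix sums: tail[j] = P(int score >= offset + j)
        self._tail = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])

    def total_mass(self) -> float:
        return float(self.pmf.sum() + self.neg_inf_mass)

    def p_value_int(self, k) -> np.ndarray:
        """Upper-tail probability for integer bin score(s) k."""
        k = np.asarray(k)
        idx = np.clip(k - self.offset, 0, len(self.pmf)).astype(int)
        out = self._tail[idx]
        out = np.where(k < self.offset, 1.0, out)
        return out

    def p_value(self, score: float) -> float:
        """P(null score >= score), evaluated at the score's bin."""
        if score == -np.inf:
            return 1.0
        return float(self.p_value_int(int(round(score / self.delta))))


def score_distribution(pwm, background=None, granularity=1e-3) -> ScoreDistribution:
    return ScoreDistribution(pwm, background=background, granularity=granularity)


# ---------------------------------------------------------------------------
# scanning


def _scan_one_strand(seq_int: np.ndarray, dist: ScoreDistribution):
    """Scores and bin p-values at every valid window start on one strand."""
    L = dist.bins.shape[0]
    if len(seq_int) < L:
        return np.array([], dtype=int), np.array([]), np.array([])
    windows = np.lib.stride_tricks.sliding_window_view(seq_int, L)
    valid = (windows >= 0).all(axis=1)
    pos = np.nonzero(valid)[0]
    if pos.size == 0:
        return pos, np.array([]), np.array([])
    idx = windows[pos]
    cols = np.arange(L)
    cont = dist.scores[cols, idx].sum(axis=1)
    bins = dist.bins[cols, idx].sum(axis=1)  # -inf propagates
    finite = np.isfinite(bins)
    p = np.ones(len(pos))
    if finite.any():
        p[finite] = dist.p_value_int(bins[finite].astype(int))
    return pos, cont, p


def scan(
    promoter: Promoter,
    pwm: PositionWeightMatrix,
    config: MotifScanConfig = MotifScanConfig(),
    dist: ScoreDistribution | None = None,
    dist_rc: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """All positions with p <= p_threshold, both strands, sorted by offset.

    Windows containing N are skipped. Minus-strand hits are reported at the
    match start in the promoter's forward coordinates.
    """
    if dist is None:
        dist = score_distribution(pwm, config.background, config.score_granularity)
    seq_int = encode_sequence(promoter.sequence)
    hits = []
    pos, scores, pvals = _scan_one_strand(seq_int, dist)
    for i, s, p in zip(pos, scores, pvals):
        if p <= config.p_threshold:
            hits.append(
                MotifHit(
                    tf=pwm.tf_name,
                    gene=promoter.gene_id,
                    offset=report_coord(promoter.start + int(i)),
                    strand="+",
                    score=float(s),
                    p_value=float(p),
                )
            )
    if config.both_strands:
        rc_pwm = pwm.reverse_complement()
        if dist_rc is None:
            dist_rc = score_distribution(
                rc_pwm, config.background, config.score_granularity
            )
        pos, scores, pvals = _scan_one_strand(seq_int, dist_rc)
        for i, s, p in zip(pos, scores, pvals):
            if p <= config.p_threshold:
                hits.append(
                    MotifHit(
                        tf=pwm.tf_name,
                        gene=promoter.gene_id,
                        offset=report_coord(promoter.start + int(i)),
                        strand="-",
                        score=float(s),
                        p_value=float(p),
                    )
                )
    hits.sort(key=lambda h: (internal_coord(h.offset), h.strand))
    return hits


def scan_promoters(
    promoters: list[Promoter],
    pwms: list[PositionWeightMatrix],
    config: MotifScanConfig = MotifScanConfig(),
) -> list[MotifHit]:
    """Scan every promoter with every PWM, caching the null per motif."""
    hits: list[MotifHit] = []
    for pwm in pwms:
        dist = score_distribution(pwm, config.background, config.score_granularity)
        dist_rc = (
            score_distribution(
                pwm.reverse_complement(), config.background, config.score_granularity
            )
            if config.both_strands
            else None
        )
        for prom in promoters:
            hits.extend(scan(prom, pwm, config, dist=dist, dist_rc=dist_rc))
    return hits


def build_prior(
    hits: list[MotifHit],
    tf_list: list[str],
    gene_list: list[str],
    motif_to_tf: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Binary TF x gene prior: 1 iff the TF has >= 1 hit in the promoter.

    Multiple motifs mapping to one TF (via ``motif_to_tf``) are OR-ed.
    """
    prior = pd.DataFrame(0, index=list(tf_list), columns=list(gene_list), dtype=int)
    tf_set, gene_set = set(tf_list), set(gene_list)
    for h in hits:
        tf = motif_to_tf.get(h.tf, h.tf) if motif_to_tf else h.tf
        if tf not in tf_set:
            raise MotifError(f"hit references unknown TF {tf!r}")
        if h.gene not in gene_set:
            raise MotifError(f"hit references unknown gene {h.gene!r}")
        prior.at[tf, h.gene] = 1
    return prior


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.tf, h.gene, h.offset, h.strand, h.score, h.p_value) for h in hits],
        columns=["tf", "gene", "offset", "strand", "score", "p_value"],
    )


# ---------------------------------------------------------------------------
# IUPAC consensus scanning (ETV2 site logic)


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise MotifError(f"invalid IUPAC letter {ch!r} in pattern")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def iupac_reverse_complement(pattern: str) -> str:
    try:
        return "".join(_IUPAC_COMPLEMENT[ch] for ch in reversed(pattern.upper()))
    except KeyError as exc:
        raise MotifError(f"invalid IUPAC letter {exc.args[0]!r} in pattern") from None


def consensus_scan(
    sequence: str,
    pattern: str = ETV2_CONSENSUS,
    both_strands: bool = True,
    tss_start: int | None = None,
) -> list[tuple[int, str]]:
    """Exact IUPAC matches of ``pattern`` (default the ETV2 site CCGGAW).

    Reverse-strand matches are forward occurrences of the reverse-complement
    pattern, reported at their forward start. Offsets are TSS-relative
    (no-zero convention) when ``tss_start`` (internal offset of the first
    base) is given, else plain 0-based indices.
    """
    seq = sequence.upper()
    out = []
    for m in _iupac_regex(pattern).finditer(seq):
        out.append((m.start(), "+"))
    if both_strands:
        for m in _iupac_regex(iupac_reverse_complement(pattern)).finditer(seq):
            out.append((m.start(), "-"))
    if tss_start is not None:
        out = [(report_coord(tss_start + i), s) for i, s in out]
        out.sort(key=lambda t: (internal_coord(t[0]), t[1]))
    else:
        out.sort()
    return out
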