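"""Position weight matrices, symmetry-constrained EM motif discovery,
and threshold-based scanning.

The motif model is the standard log-odds PWM.  Operator motifs of
bacterial TFs are usually dyad-symmetric (a homodimer binds two
half-sites), so both PWM construction and EM discovery can constrain the
frequency matrix to a symmetry class:

``palindrome``
    the matrix equals its own reverse complement;
``inverted_repeat``
    two reverse-complementary half-sites separated by a fixed-width
    spacer whose columns are held at background;
``direct_repeat``
    two identical, tandem half-sites with a background spacer;
``none``
    unconstrained.

Discovery is a ZOOPS (zero-or-one occurrence per sequence) EM: each
region carries at most one site, on either strand, with prior
probability ``gamma``.  The M-step pools expected base counts over
symmetry-equivalent cells, which is the exact maximizer under the
constraint, so the penalized log-likelihood is non-decreasing at every
iteration (asserted).

Scanning follows the comparative-genomics convention of a training-set
minimum threshold: a profile's detection threshold is the lowest score
among its own training sites, so every training site is rediscovered by
construction and the profile generalizes exactly as far as its weakest
known member.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genomes import UpstreamRegion, reverse_complement

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_ENCODE = np.full(256, 4, dtype=np.int64)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_COMP = np.array([3, 2, 1, 0, 4])

UNIFORM = np.full(4, 0.25)


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to indices 0..3 (4 for any non-ACGT base)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _revcomp_matrix(m: np.ndarray) -> np.ndarray:
    return m[::-1, ::-1]


def project_symmetry(
    counts: np.ndarray,
    symmetry: str,
    spacer: int = 0,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Project a (width x 4) count matrix onto a symmetry class.

    Pools counts over symmetry-equivalent cells (the constrained
    maximum-likelihood estimate); spacer columns of repeat symmetries
    are replaced by background-proportional counts.  Idempotent.
    """
    counts = np.asarray(counts, dtype=float)
    w = counts.shape[0]
    if symmetry == "none":
        return counts.copy()
    if symmetry == "palindrome":
        return (counts + _revcomp_matrix(counts)) / 2.0
    if symmetry not in ("direct_repeat", "inverted_repeat"):
        raise ValueError(f"unknown symmetry {symmetry!r}")
    if background is None:
        background = UNIFORM
    half = (w - spacer) // 2
    if 2 * half + spacer != w:
        raise ValueError(f"width {w} incompatible with spacer {spacer}")
    left, right = counts[:half], counts[w - half :]
    out = counts.copy()
    if symmetry == "direct_repeat":
        avg = (left + right) / 2.0
        out[:half], out[w - half :] = avg, avg
    else:
        avg = (left + _revcomp_matrix(right)) / 2.0
        out[:half], out[w - half :] = avg, _revcomp_matrix(avg)
    for c in range(half, w - half):
        out[c] = counts[c].sum() * background
    return out


@dataclass
class PWM:
    """Count-based position weight matrix with optional dyad symmetry."""

    counts: np.ndarray  # (width, 4), A C G T
    pseudocount: float = 0.5
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())
    symmetry: str = "none"
    spacer: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be (width, 4)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        # background-proportional pseudocounts: total prior mass 4*pc per
        # column, split by background (reduces to Laplace pc-per-cell for
        # a uniform background)
        f = self.counts + 4.0 * self.pseudocount * self.background
        return f / f.sum(axis=1, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.frequencies / self.background)

    @property
    def information_content(self) -> float:
        return float(self.information_per_column.sum())

    @property
    def information_per_column(self) -> np.ndarray:
        f = self.frequencies
        return np.sum(f * np.log2(f / self.background), axis=1)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.frequencies.argmax(axis=1))

    def max_score(self) -> float:
        return float(np.add.reduce(self.log_odds.max(axis=1)))

    def reverse_complement(self) -> "PWM":
        return PWM(
            counts=_revcomp_matrix(self.counts),
            pseudocount=self.pseudocount,
            background=self.background.copy(),
            symmetry=self.symmetry,
            spacer=self.spacer,
        )


def build_pwm(
    site_sequences: list[str],
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    symmetry: str = "none",
    spacer: int = 0,
) -> PWM:
    """Count-based PWM from aligned, equal-length sites over ACGT.

    Symmetry is enforced by projecting the count matrix (see
    :func:`project_symmetry`), so e.g. a palindromic PWM equals its own
    reverse complement exactly.
    """
    if len(site_sequences) < 2:
        raise ValueError("need at least 2 site sequences")
    w = len(site_sequences[0])
    if any(len(s) != w for s in site_sequences):
        raise ValueError("site sequences must have equal length")
    bg = UNIFORM.copy() if background is None else np.asarray(background, dtype=float)
    counts = np.zeros((w, 4))
    for s in site_sequences:
        idx = encode(s)
        if np.any(idx == 4):
            raise ValueError(f"non-ACGT base in site {s!r}")
        counts[np.arange(w), idx] += 1.0
    counts = project_symmetry(counts, symmetry, spacer, bg)
    return PWM(counts=counts, pseudocount=pseudocount, background=bg,
               symmetry=symmetry, spacer=spacer)


# ---------------------------------------------------------------------------
# scoring


def _window_scores(
    log_odds: np.ndarray, idx: np.ndarray, descending: bool = False
) -> np.ndarray:
    """Sum of per-column log-odds at every window start (sequential in
    column order, so a position-by-position rescoring loop reproduces the
    result bit for bit).  Windows containing a non-ACGT base score NaN.

    ``descending`` sums columns last-to-first; used for the reverse
    strand, where the natural order is that of the reverse-complemented
    word, not of the matrix as stored.
    """
    w = log_odds.shape[0]
    n = len(idx) - w + 1
    if n <= 0:
        return np.empty(0)
    lo = np.concatenate([log_odds, np.full((w, 1), np.nan)], axis=1)
    acc = np.zeros(n)
    order = range(w - 1, -1, -1) if descending else range(w)
    for i in order:
        acc = acc + lo[i, idx[i : i + n]]
    return acc


@dataclass
class ScanScores:
    forward: np.ndarray
    reverse: np.ndarray

    @property
    def best(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.fmax(self.forward, self.reverse)

    @property
    def strand(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(np.fmax(self.forward, self.reverse) == self.forward, "+", "-")


def score_sequence(pwm: PWM, sequence: str) -> ScanScores:
    """Log-odds score of every window on both strands.

    The reverse-strand score at offset o is the score of the
    reverse-complemented window, i.e. the forward score of the
    reverse-complement PWM at o.
    """
    if len(sequence) < pwm.width:
        raise ValueError("sequence shorter than PWM width")
    idx = encode(sequence)
    lo = pwm.log_odds
    return ScanScores(
        forward=_window_scores(lo, idx),
        reverse=_window_scores(_revcomp_matrix(lo), idx, descending=True),
    )


def score_site(pwm: PWM, word: str) -> float:
    """Score one word of exactly PWM width (forward orientation)."""
    if len(word) != pwm.width:
        raise ValueError("word length must equal PWM width")
    return float(_window_scores(pwm.log_odds, encode(word))[0])


@dataclass
class Site:
    """One PWM match inside an upstream region."""

    region: str  # operon id
    genome: str
    offset: int  # 0-based start within the region
    strand: str  # relative to the region's coding strand
    sequence: str
    score: float


@dataclass
class Profile:
    """A PWM paired with its training sites and detection threshold."""

    pwm: PWM
    training_sites: list[str]
    name: str = ""
    threshold: float = field(init=False)

    def __post_init__(self) -> None:
        self.threshold = set_threshold(self.pwm, self.training_sites)


def set_threshold(pwm: PWM, training_sites: list[str]) -> float:
    """Detection threshold = lowest score observed in the training set."""
    if not training_sites:
        raise ValueError("empty training set")
    return min(score_site(pwm, s) for s in training_sites)


def scan(profile: Profile, regions: list[UpstreamRegion]) -> list[Site]:
    """All positions scoring at least the profile threshold.

    Opposite-strand hits at the same offset (same center) are reported
    once, on the better-scoring strand (ties go to +).  Output is sorted
    by region id then offset.
    """
    out: list[Site] = []
    w = profile.pwm.width
    for region in sorted(regions, key=lambda r: (r.genome, r.operon)):
        if region.empty or len(region.sequence) < w:
            continue
        scores = score_sequence(profile.pwm, region.sequence)
        best = scores.best
        hits = np.flatnonzero(best >= profile.threshold)
        for off in hits:
            fwd, rev = scores.forward[off], scores.reverse[off]
            strand = "+" if (np.isnan(rev) or (not np.isnan(fwd) and fwd >= rev)) else "-"
            word = region.sequence[off : off + w]
            if strand == "-":
                word = reverse_complement(word)
            out.append(
                Site(
                    region=region.operon,
                    genome=region.genome,
                    offset=int(off),
                    strand=strand,
                    sequence=word,
                    score=float(best[off]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# EM discovery


@dataclass
class MotifResult:
    pwm: PWM
    sites: list[Site]
    information_content: float  # total bits of the selected PWM
    log_likelihood: float  # the model-selection objective (penalized ZOOPS)
    n_iterations: int
    width: int
    restart: int
    objective_trace: list[float] = field(default_factory=list)


def estimate_background(sequences: list[str]) -> np.ndarray:
    """Order-0 background from pooled sequences, counted on both strands.

    Double-stranded counting makes the background complement-symmetric
    (A=T, C=G), which both reflects how scanning works and keeps
    palindromic PWMs exactly equal to their reverse complements under
    background-proportional pseudocounts.
    """
    counts = np.zeros(5)
    for s in sequences:
        counts += np.bincount(encode(s), minlength=5)
    freq = counts[:4] + 1.0
    freq = (freq + freq[::-1]) / 2.0  # pool with the complementary strand
    return freq / freq.sum()


def _em_run(
    encoded: list[np.ndarray],
    width: int,
    symmetry: str,
    spacer: int,
    background: np.ndarray,
    init_counts: np.ndarray,
    gamma: float,
    pseudocount: float,
    max_iter: int,
    tol: float,
) -> tuple[PWM, float, int, list[float], list[tuple[int, int, str, float]]]:
    """One EM run from a fixed initialization.

    Returns the PWM, the penalized log-likelihood, iteration count, the
    objective trace, and the MAP site per region (index, offset, strand,
    posterior mass of having a site).
    """
    counts = project_symmetry(init_counts, symmetry, spacer, background)
    pwm = PWM(counts, pseudocount, background, symmetry, spacer)
    comp_idx = [_COMP[idx] for idx in encoded]
    prev_obj = -np.inf
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        lo = pwm.log_odds
        lo_rc = _revcomp_matrix(lo)
        new_counts = np.zeros((width, 4 + 1))
        # Dirichlet prior term of the CURRENT pwm: the penalized marginal
        # log-likelihood L(pwm_k) is what EM drives monotonically upward
        obj = 4.0 * pseudocount * float((background * np.log2(pwm.frequencies)).sum())
        responsibilities = []
        for idx, cidx in zip(encoded, comp_idx):
            n = len(idx) - width + 1
            llr_f = _window_scores(lo, idx)
            llr_r = _window_scores(lo_rc, idx)
            llr = np.concatenate([llr_f, llr_r])
            llr = np.where(np.isnan(llr), -np.inf, llr)
            prior = gamma / (2 * n)
            m = max(llr.max(), 0.0)
            weights = prior * np.exp2(llr - m)
            z = (1.0 - gamma) * np.exp2(-m) + weights.sum()
            obj += np.log2(z) + m
            post = weights / z
            responsibilities.append(post)
            wf, wr = post[:n], post[n:]
            for i in range(width):
                np.add.at(new_counts[i], idx[i : i + n], wf)
                np.add.at(new_counts[i], cidx[width - 1 - i : width - 1 - i + n], wr)
        new_counts = project_symmetry(new_counts[:, :4], symmetry, spacer, background)
        pwm = PWM(new_counts, pseudocount, background, symmetry, spacer)
        trace.append(obj)
        if obj < prev_obj - 1e-8:
            raise AssertionError(
                f"EM objective decreased: {prev_obj} -> {obj} at iteration {n_iter}"
            )
        if np.isfinite(prev_obj) and abs(obj - prev_obj) <= tol * max(1.0, abs(prev_obj)):
            prev_obj = obj
            break
        prev_obj = obj

    site_calls = []
    for r, post in enumerate(responsibilities):
        n = len(post) // 2
        if post.sum() > 0.5:  # region more likely than not to hold a site
            j = int(post.argmax())
            strand = "+" if j < n else "-"
            site_calls.append((r, j % n, strand, float(post.sum())))
    return pwm, float(prev_obj), n_iter, trace, site_calls


def _seed_counts(
    encoded: list[np.ndarray],
    width: int,
    background: np.ndarray,
    rng: np.random.Generator,
    weight: float = 5.0,
) -> np.ndarray:
    """Initialize from a word drawn from the data (k-mer seeding)."""
    eligible = [idx for idx in encoded if len(idx) >= width]
    idx = eligible[rng.integers(len(eligible))]
    start = rng.integers(len(idx) - width + 1)
    word = idx[start : start + width]
    counts = np.tile(background, (width, 1)).astype(float)
    for i, b in enumerate(word):
        if b < 4:
            counts[i, b] += weight
    return counts


def discover_motif(
    regions: list[UpstreamRegion] | list[str],
    width_range: tuple[int, int] = (14, 24),
    width_step: int = 2,
    symmetry: str = "palindrome",
    n_restarts: int = 20,
    seed: int = 0,
    gamma: float = 0.8,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    spacer_range: tuple[int, int] = (0, 4),
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MotifResult:
    """Symmetry-constrained ZOOPS EM motif discovery.

    Runs EM for every width in ``width_range`` (and every half-site
    spacer for repeat symmetries) from ``n_restarts`` seeded word
    initializations, and returns the solution with the highest penalized
    marginal log-likelihood.  Because the likelihood is computed over
    whole regions (motif columns relative to background), it is
    comparable across widths, and the Dirichlet penalty charges
    uninformative flank columns, so the selected width tracks the
    informative core instead of always growing.  Ties break to the
    smallest width then the lowest restart index.  Deterministic given
    ``seed``.
    """
    seqs = [r.sequence if isinstance(r, UpstreamRegion) else r for r in regions]
    region_ids = [
        (r.operon, r.genome) if isinstance(r, UpstreamRegion) else (f"region{i}", "")
        for i, r in enumerate(regions)
    ]
    if len(seqs) < 3:
        raise ValueError("need at least 3 regions")
    bg = estimate_background(seqs) if background is None else np.asarray(background, float)

    best: MotifResult | None = None
    rng = np.random.default_rng(seed)
    for width in range(width_range[0], width_range[1] + 1, width_step):
        keep = [i for i, s in enumerate(seqs) if len(s) >= width]
        if not keep:
            continue
        encoded = [encode(seqs[i]) for i in keep]
        if symmetry in ("direct_repeat", "inverted_repeat"):
            spacers = [
                sp
                for sp in range(spacer_range[0], spacer_range[1] + 1)
                if (width - sp) > 0 and (width - sp) % 2 == 0
            ]
        else:
            spacers = [0]
        for spacer in spacers:
            for restart in range(n_restarts):
                init = _seed_counts(encoded, width, bg, rng)
                pwm, obj, n_iter, trace, calls = _em_run(
                    encoded, width, symmetry, spacer, bg, init,
                    gamma, pseudocount, max_iter, tol,
                )
                key = (obj, -width, -restart)
                if best is None or key > (
                    best.log_likelihood, -best.width, -best.restart
                ):
                    sites = []
                    for r, off, strand, _ in calls:
                        seq_idx = keep[r]
                        word = seqs[seq_idx][off : off + width]
                        if strand == "-":
                            word = reverse_complement(word)
                        sites.append(
                            Site(
                                region=region_ids[seq_idx][0],
                                genome=region_ids[seq_idx][1],
                                offset=off,
                                strand=strand,
                                sequence=word,
                                score=score_site(pwm, word),
                            )
                        )
                    best = MotifResult(
                        pwm=pwm, sites=sites,
                        information_content=pwm.information_content,
                        log_likelihood=obj, n_iterations=n_iter,
                        width=width, restart=restart, objective_trace=trace,
                    )
    if best is None:
        raise ValueError("all regions shorter than the smallest width")
    return best


# ---------------------------------------------------------------------------
# MEME minimal format I/O

_SYMMETRIES = ("palindrome", "direct_repeat", "inverted_repeat", "none")


def write_meme(profiles: list[Profile] | list[PWM], path: str | Path,
               names: list[str] | None = None) -> None:
    """Write PWMs in MEME minimal motif format.

    The symmetry class rides along in the alternate-name slot of the
    MOTIF line; nsites is the rounded total count mass of the matrix.
    """
    pwms, labels = [], []
    for i, p in enumerate(profiles):
        if isinstance(p, Profile):
            pwms.append(p.pwm)
            labels.append(p.name or f"motif_{i + 1}")
        else:
            pwms.append(p)
            labels.append(names[i] if names else f"motif_{i + 1}")
    bg = pwms[0].background if pwms else UNIFORM
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate(BASES)) + "\n\n")
        for pwm, label in zip(pwms, labels):
            nsites = max(int(round(pwm.counts.sum(axis=1).max())), 1)
            fh.write(f"MOTIF {label} {pwm.symmetry}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= {nsites} E= 0\n"
            )
            for row in pwm.frequencies:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path, pseudocount: float = 0.0) -> dict[str, PWM]:
    """Read PWMs from MEME minimal motif format."""
    text = Path(path).read_text()
    bg = UNIFORM.copy()
    m = re.search(
        r"Background letter frequencies.*?\nA ([\d.eE+-]+) C ([\d.eE+-]+) "
        r"G ([\d.eE+-]+) T ([\d.eE+-]+)",
        text,
        re.S,
    )
    if m:
        bg = np.array([float(x) for x in m.groups()])
        bg = bg / bg.sum()
    out: dict[str, PWM] = {}
    motif_re = re.compile(
        r"MOTIF (\S+)(?: (\S+))?\s*\nletter-probability matrix: alength= 4 "
        r"w= (\d+) nsites= (\d+)[^\n]*\n((?:\s*[\d.eE+-]+[^\n]*\n)+)"
    )
    for m in motif_re.finditer(text):
        name, alt, w, nsites, block = m.groups()
        rows = [
            [float(x) for x in line.split()]
            for line in block.strip().splitlines()
        ]
        freq = np.array(rows)
        if freq.shape != (int(w), 4):
            raise ValueError(f"motif {name}: matrix shape {freq.shape} != ({w}, 4)")
        symmetry = alt if alt in _SYMMETRIES else "none"
        out[name] = PWM(
            counts=freq * int(nsites),
            pseudocount=pseudocount,
            background=bg,
            symmetry=symmetry,
        )
    return out


def sites_to_tsv(sites: list[Site], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\tregion\toffset\tstrand\tsequence\tscore\n")
        for s in sites:
            fh.write(
                f"{s.genome}\t{s.region}\t{s.offset}\t{s.strand}\t{s.sequence}\t{s.score:.4f}\n"
            )


def sites_to_gff(sites: list[Site], path: str | Path) -> None:
    """Sites as GFF3 TF_binding_site features in region-local coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, s in enumerate(sites, 1):
            fh.write(
                f"{s.region}\tregulonkit\tTF_binding_site\t{s.offset + 1}\t"
                f"{s.offset + len(s.sequence)}\t{s.score:.4f}\t{s.strand}\t.\t"
                f"ID=site{i:05d};genome={s.genome}\n"
            )
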