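"""Self-contained xenograft fixtures: diverged genomes, reads, and alignments.

A validation run needs ground truth that no real PDX dataset provides, so
this module builds the whole experiment from scratch:

1. :func:`evolve_pair` — evolve two colinear genomes (graft-like and
   host-like) from a common ancestor under a two-branch substitution model
   with a conserved fraction at lower divergence and rare short indels.
   Coordinate maps between each genome and the ancestor are recorded, so the
   homologous locus of any read is computable in both genomes.
2. :func:`simulate_reads` — uniform single- or paired-end reads with per-base
   errors and a recorded truth table (species, coordinate, strand).
3. :func:`mix_read_sets` — deterministic graft:host mixtures at exact ratios.
4. :func:`emulate_alignments` — a deterministic stand-in for an external
   aligner: each read is aligned to its homologous window in *both* genomes
   and emitted as a BAM record with CIGAR and a SAM-conforming NM tag
   (mismatches + inserted + deleted bases). Reads whose best alignment falls
   below an identity floor are emitted unmapped.
5. :func:`evaluate_classification` — confusion matrix and the two headline
   percentages (host removal, graft retention) against the truth table.

All randomness flows from one user seed through numpy ``SeedSequence``
spawn keys, so every operation is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pysam
from Bio import Align

__all__ = [
    "GenomePair",
    "SimulatedReadSet",
    "EvaluationResult",
    "evolve_pair",
    "simulate_reads",
    "mix_read_sets",
    "emulate_alignments",
    "evaluate_classification",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_TO_ASCII = bytes.maketrans(bytes(range(4)), b"ACGT")

# Emulated-aligner scoring: match +1, mismatch -4, gap open -6, extend -1
# (first gap base costs -6), free end gaps on both sequences so that read
# overhangs become soft clips. Mapping floor: <80% of read bases matching.
ALIGNER_MATCH = 1.0
ALIGNER_MISMATCH = -4.0
ALIGNER_GAP_OPEN = -6.0
ALIGNER_GAP_EXTEND = -1.0
DEFAULT_IDENTITY_FLOOR = 0.8

CONSERVED_BLOCK = 1000  # bp per conserved interval


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for one operation, derived from the user seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _codes_to_str(codes: np.ndarray) -> str:
    return codes.astype(np.uint8).tobytes().translate(_CODE_TO_ASCII).decode()


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[..., ::-1]


# ---------------------------------------------------------------------------
# Genome pair evolution
# ---------------------------------------------------------------------------

@dataclass
class GenomePair:
    """Two colinear genomes evolved from a common ancestor.

    ``anc2graft[i]`` is the graft-genome coordinate of ancestor site ``i``
    (−1 if deleted on the graft branch); ``graft2anc`` is the inverse (−1
    for bases inserted on the graft branch); likewise for the host.
    """

    ancestor: str
    graft_genome: str
    host_genome: str
    divergence: float
    conserved_fraction: float
    conserved_divergence: float
    indel_rate: float
    seed: int
    conserved_intervals: list = field(default_factory=list)
    anc2graft: np.ndarray = None
    anc2host: np.ndarray = None
    graft2anc: np.ndarray = None
    host2anc: np.ndarray = None
    _codes: dict = field(default_factory=dict, repr=False)
    _chain_cache: dict = field(default_factory=dict, repr=False)

    def genome_codes(self, species: str) -> np.ndarray:
        if species not in self._codes:
            seq = self.graft_genome if species == "graft" else self.host_genome
            raw = np.frombuffer(seq.encode(), dtype=np.uint8)
            codes = np.empty(raw.size, dtype=np.uint8)
            for c, b in enumerate(b"ACGT"):
                codes[raw == b] = c
            self._codes[species] = codes
        return self._codes[species]

    def maps(self, species: str):
        if species == "graft":
            return self.graft2anc, self.anc2graft
        return self.host2anc, self.anc2host

    def _step_cums(self, key: str) -> np.ndarray:
        """Cumulative count of "breaks" in a coordinate map.

        ``C[k]`` counts positions ``i < k`` where map[i] is −1 or map[i+1]
        is not map[i]+1; a window maps contiguously iff its break count is 0.
        """
        if key not in self._chain_cache:
            m = {
                "graft2anc": self.graft2anc,
                "host2anc": self.host2anc,
                "anc2graft": self.anc2graft,
                "anc2host": self.anc2host,
            }[key]
            bad = (m[:-1] == -1) | (m[1:] != m[:-1] + 1)
            self._chain_cache[key] = np.concatenate(
                ([0], np.cumsum(bad.astype(np.int64)))
            )
        return self._chain_cache[key]


def _evolve_branch(anc_codes: np.ndarray, p_site: np.ndarray, indel_rate: float,
                   rng: np.random.Generator):
    """Apply substitutions and indels to one branch; return codes and maps."""
    L = anc_codes.size
    codes = anc_codes.copy()
    sub_mask = rng.random(L) < p_site
    n_sub = int(sub_mask.sum())
    codes[sub_mask] = (codes[sub_mask] + rng.integers(1, 4, n_sub).astype(np.uint8)) % 4

    del_mask = np.zeros(L, dtype=bool)
    insertions: dict[int, np.ndarray] = {}
    if indel_rate > 0:
        for pos in np.nonzero(rng.random(L) < indel_rate)[0]:
            length = min(int(rng.geometric(0.5)), 10)
            if rng.random() < 0.5:
                del_mask[pos : pos + length] = True
            else:
                insertions[int(pos)] = rng.integers(0, 4, length).astype(np.uint8)

    keep = ~del_mask
    ins_arr = np.zeros(L, dtype=np.int64)
    for pos, bases in insertions.items():
        ins_arr[pos] = bases.size
    cum_ins_incl = np.cumsum(ins_arr)  # inserted bases at positions <= i
    kept_before = np.cumsum(keep) - keep  # kept sites among [0, i)

    anc2gen = np.where(keep, kept_before + cum_ins_incl, -1).astype(np.int64)
    glen = int(keep.sum() + cum_ins_incl[-1] if L else 0)
    gen = np.empty(glen, dtype=np.uint8)
    kept_idx = np.nonzero(keep)[0]
    gen[anc2gen[kept_idx]] = codes[kept_idx]
    for pos, bases in insertions.items():
        start = int(kept_before[pos] + cum_ins_incl[pos] - bases.size)
        gen[start : start + bases.size] = bases
    gen2anc = np.full(glen, -1, dtype=np.int64)
    gen2anc[anc2gen[kept_idx]] = kept_idx
    return gen, anc2gen, gen2anc


def evolve_pair(
    length: int,
    divergence: float = 0.08,
    conserved_fraction: float = 0.10,
    conserved_divergence: float = 0.01,
    indel_rate: float = 1e-4,
    seed: int = 0,
) -> GenomePair:
    """Evolve a colinear graft/host genome pair from a random ancestor.

    Each branch substitutes every site independently with probability
    ``divergence`` (``conserved_divergence`` inside conserved intervals;
    fixed 1 kb blocks spread evenly with a random offset) and applies rare
    indels (geometric lengths, mean 2 bp, capped at 10). Deterministic for a
    given seed.
    """
    for name, p in (
        ("divergence", divergence),
        ("conserved_fraction", conserved_fraction),
        ("conserved_divergence", conserved_divergence),
        ("indel_rate", indel_rate),
    ):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be a probability, got {p}")
    if length < 1000:
        raise ValueError("genome length must be at least 1000")

    rng_anc = _rng(seed, 0)
    anc = rng_anc.integers(0, 4, length).astype(np.uint8)

    intervals: list[tuple[int, int]] = []
    p_site = np.full(length, divergence)
    n_blocks = int(round(conserved_fraction * length / CONSERVED_BLOCK))
    if n_blocks > 0:
        stride = length // n_blocks
        block = min(CONSERVED_BLOCK, stride)
        for i in range(n_blocks):
            lo = i * stride
            off = int(rng_anc.integers(0, max(1, stride - block + 1)))
            start = lo + off
            intervals.append((start, start + block))
            p_site[start : start + block] = conserved_divergence

    g_codes, anc2graft, graft2anc = _evolve_branch(anc, p_site, indel_rate, _rng(seed, 1))
    h_codes, anc2host, host2anc = _evolve_branch(anc, p_site, indel_rate, _rng(seed, 2))

    return GenomePair(
        ancestor=_codes_to_str(anc),
        graft_genome=_codes_to_str(g_codes),
        host_genome=_codes_to_str(h_codes),
        divergence=divergence,
        conserved_fraction=conserved_fraction,
        conserved_divergence=conserved_divergence,
        indel_rate=indel_rate,
        seed=seed,
        conserved_intervals=intervals,
        anc2graft=anc2graft,
        anc2host=anc2host,
        graft2anc=graft2anc,
        host2anc=host2anc,
    )


# ---------------------------------------------------------------------------
# Read simulation and mixing
# ---------------------------------------------------------------------------

@dataclass
class SimulatedReadSet:
    """Reads with full ground truth.

    ``codes1``/``codes2`` hold base codes in as-sequenced orientation;
    ``starts*`` are 0-based leftmost coordinates on the origin genome;
    ``rev1``/``rev2`` flag reverse-complemented mates. ``species`` gives the
    origin genome of each read (pair).
    """

    names: np.ndarray
    species: np.ndarray
    paired: bool
    read_length: int
    error_rate: float
    insert_mean: Optional[float]
    insert_sd: Optional[float]
    seed: int
    codes1: np.ndarray = None
    starts1: np.ndarray = None
    rev1: np.ndarray = None
    codes2: Optional[np.ndarray] = None
    starts2: Optional[np.ndarray] = None
    rev2: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.names)

    def truth(self) -> Dict[str, tuple]:
        """name -> (species, 1-based mate1 position, strand of mate1)."""
        return {
            str(n): (str(sp), int(s) + 1, "-" if r else "+")
            for n, sp, s, r in zip(self.names, self.species, self.starts1, self.rev1)
        }

    def sequences(self, mate: int = 1) -> list[str]:
        codes = self.codes1 if mate == 1 else self.codes2
        return [_codes_to_str(row) for row in codes]

    def to_fastq(self, path1: str, path2: Optional[str] = None) -> None:
        qual = "I" * self.read_length
        with open(path1, "w") as fh1:
            for name, row in zip(self.names, self.codes1):
                suffix = "/1" if self.paired else ""
                fh1.write(f"@{name}{suffix}\n{_codes_to_str(row)}\n+\n{qual}\n")
        if self.paired:
            if path2 is None:
                raise ValueError("paired read set needs a second FASTQ path")
            with open(path2, "w") as fh2:
                for name, row in zip(self.names, self.codes2):
                    fh2.write(f"@{name}/2\n{_codes_to_str(row)}\n+\n{qual}\n")

    def to_truth_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("name\tspecies\tchrom\tpos\tstrand\n")
            for name, (sp, pos, strand) in self.truth().items():
                fh.write(f"{name}\t{sp}\tsynth\t{pos}\t{strand}\n")


def _apply_errors(codes: np.ndarray, error_rate: float, rng: np.random.Generator) -> None:
    if error_rate <= 0:
        return
    mask = rng.random(codes.shape) < error_rate
    n = int(mask.sum())
    codes[mask] = (codes[mask] + rng.integers(1, 4, n).astype(np.uint8)) % 4


def simulate_reads(
    genome: str | np.ndarray,
    n: int,
    read_length: int = 100,
    paired: bool = True,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    error_rate: float = 0.01,
    seed: int = 0,
    species: str = "graft",
    name_prefix: Optional[str] = None,
) -> SimulatedReadSet:
    """Simulate ``n`` reads (or read pairs) uniformly from one genome.

    Fragments start uniformly, land on either strand with equal probability,
    and pair mates face each other (FR orientation) at Normal insert sizes
    truncated below at the read length. Errors are independent per base.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if isinstance(genome, str):
        raw = np.frombuffer(genome.encode(), dtype=np.uint8)
        gcodes = np.empty(raw.size, dtype=np.uint8)
        for c, b in enumerate(b"ACGT"):
            gcodes[raw == b] = c
    else:
        gcodes = genome
    glen = gcodes.size
    if read_length > glen:
        raise ValueError("read_length exceeds genome length")

    rng = _rng(seed, 3)
    prefix = name_prefix or species
    names = np.array([f"{prefix}_{i}" for i in range(n)], dtype=object)
    sp = np.array([species] * n, dtype=object)
    offsets = np.arange(read_length)

    if not paired:
        starts = rng.integers(0, glen - read_length + 1, n)
        rev = rng.random(n) < 0.5
        fwd = gcodes[starts[:, None] + offsets]
        codes = np.where(rev[:, None], _revcomp_codes(fwd), fwd).astype(np.uint8)
        _apply_errors(codes, error_rate, rng)
        return SimulatedReadSet(
            names=names, species=sp, paired=False, read_length=read_length,
            error_rate=error_rate, insert_mean=None, insert_sd=None, seed=seed,
            codes1=codes, starts1=starts, rev1=rev,
        )

    frag = np.clip(
        np.rint(rng.normal(insert_mean, insert_sd, n)).astype(np.int64),
        read_length,
        glen,
    )
    fs = rng.integers(0, glen - frag + 1)
    rev = rng.random(n) < 0.5  # fragment sequenced from the minus strand
    left = fs
    right = fs + frag - read_length
    starts1 = np.where(~rev, left, right)
    starts2 = np.where(~rev, right, left)
    fwd1 = gcodes[starts1[:, None] + offsets]
    fwd2 = gcodes[starts2[:, None] + offsets]
    codes1 = np.where(rev[:, None], _revcomp_codes(fwd1), fwd1).astype(np.uint8)
    codes2 = np.where(~rev[:, None], _revcomp_codes(fwd2), fwd2).astype(np.uint8)
    _apply_errors(codes1, error_rate, rng)
    _apply_errors(codes2, error_rate, rng)
    return SimulatedReadSet(
        names=names, species=sp, paired=True, read_length=read_length,
        error_rate=error_rate, insert_mean=insert_mean, insert_sd=insert_sd,
        seed=seed, codes1=codes1, starts1=starts1, rev1=rev,
        codes2=codes2, starts2=starts2, rev2=~rev,
    )


def mix_read_sets(
    graft_set: SimulatedReadSet,
    host_set: SimulatedReadSet,
    graft_fraction: float,
    total_n: int,
    seed: int = 0,
) -> SimulatedReadSet:
    """Mix two read sets at an exact ratio, deterministically shuffled.

    Takes ``round(graft_fraction * total_n)`` graft reads and the remainder
    from the host set (sampled without replacement), merging truth tables.
    """
    if not (0.0 <= graft_fraction <= 1.0):
        raise ValueError("graft_fraction must be in [0, 1]")
    if graft_set.paired != host_set.paired or graft_set.read_length != host_set.read_length:
        raise ValueError("read sets must share pairedness and read length")
    n_graft = int(round(graft_fraction * total_n))
    n_host = total_n - n_graft
    if n_graft > len(graft_set) or n_host > len(host_set):
        raise ValueError("source read sets too small for requested mixture")

    rng = _rng(seed, 4)
    gi = rng.choice(len(graft_set), n_graft, replace=False)
    hi = rng.choice(len(host_set), n_host, replace=False)

    def cat(a, b):
        if a is None or b is None:
            return None
        return np.concatenate([a, b])

    order = rng.permutation(total_n)

    def pick(field_g, field_h):
        merged = cat(
            field_g[gi] if field_g is not None else None,
            field_h[hi] if field_h is not None else None,
        )
        return merged[order] if merged is not None else None

    paired = graft_set.paired
    return SimulatedReadSet(
        names=pick(graft_set.names, host_set.names),
        species=pick(graft_set.species, host_set.species),
        paired=paired,
        read_length=graft_set.read_length,
        error_rate=graft_set.error_rate,
        insert_mean=graft_set.insert_mean,
        insert_sd=graft_set.insert_sd,
        seed=seed,
        codes1=pick(graft_set.codes1, host_set.codes1),
        starts1=pick(graft_set.starts1, host_set.starts1),
        rev1=pick(graft_set.rev1, host_set.rev1),
        codes2=pick(graft_set.codes2, host_set.codes2) if paired else None,
        starts2=pick(graft_set.starts2, host_set.starts2) if paired else None,
        rev2=pick(graft_set.rev2, host_set.rev2) if paired else None,
    )


# ---------------------------------------------------------------------------
# Alignment emulation
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = ALIGNER_MATCH
    aligner.mismatch_score = ALIGNER_MISMATCH
    aligner.open_gap_score = ALIGNER_GAP_OPEN
    aligner.extend_gap_score = ALIGNER_GAP_EXTEND
    # free end gaps on both sides: window overhang costs nothing, read
    # overhang becomes soft clips
    aligner.end_gap_score = 0.0
    return aligner


def _window_positions(pair: GenomePair, origin: str, target: str,
                      starts: np.ndarray, rl: int):
    """Vectorized homologous-window lookup: target start + contiguity flag.

    A window is contiguous when its origin sites map one-to-one onto
    consecutive ancestor sites that in turn map onto consecutive target
    sites — i.e. no indel of either branch intersects it.
    """
    if origin == target:
        return starts.copy(), np.ones(starts.size, dtype=bool)
    g2a, _ = pair.maps(origin)
    _, a2g_t = pair.maps(target)
    cum_o = pair._step_cums(f"{origin}2anc")
    cum_t = pair._step_cums(f"anc2{target}")

    clean_o = (cum_o[starts + rl - 1] - cum_o[starts]) == 0
    a_s = g2a[np.clip(starts, 0, g2a.size - 1)]
    ok = clean_o & (a_s >= 0) & (a_s + rl <= a2g_t.size)
    a_idx = np.clip(a_s, 0, max(0, a2g_t.size - rl))
    clean_t = (cum_t[a_idx + rl - 1] - cum_t[a_idx]) == 0
    tstart = a2g_t[a_idx]
    ok &= clean_t & (tstart >= 0)
    return np.where(ok, tstart, -1), ok


def _align_gapped(read_fwd: str, pair: GenomePair, origin: str, target: str,
                  start: int, rl: int, aligner: Align.PairwiseAligner,
                  identity_floor: float):
    """Affine-gap alignment of one read to its homologous window.

    Returns (pos0, cigar, nm) or None if unmapped (no anchor or identity
    below the floor)."""
    target_codes = pair.genome_codes(target)
    glen = target_codes.size
    if origin == target:
        est = start
    else:
        g2a, _ = pair.maps(origin)
        _, a2g_t = pair.maps(target)
        est = None
        for j in range(rl):
            a = g2a[start + j] if start + j < g2a.size else -1
            if a < 0:
                continue
            t = a2g_t[a]
            if t < 0:
                continue
            est = int(t) - j
            break
        if est is None:
            return None
    pad = 30
    wstart = max(0, est - pad)
    wend = min(glen, est + rl + pad)
    if wend - wstart < 1:
        return None
    window = _codes_to_str(target_codes[wstart:wend])

    try:
        aln = aligner.align(window, read_fwd)[0]
    except (IndexError, ValueError):
        return None
    t_blocks, q_blocks = aln.aligned
    if len(q_blocks) == 0:
        return None

    cig: list[tuple[int, str]] = []
    matches = 0
    mismatches = 0
    ins_b = 0
    del_b = 0
    lead = int(q_blocks[0][0])
    if lead:
        cig.append((lead, "S"))
    prev_t = prev_q = None
    win_arr = np.frombuffer(window.encode(), dtype=np.uint8)
    read_arr = np.frombuffer(read_fwd.encode(), dtype=np.uint8)
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            if qs > prev_q:
                cig.append((qs - prev_q, "I"))
                ins_b += qs - prev_q
            if ts > prev_t:
                cig.append((ts - prev_t, "D"))
                del_b += ts - prev_t
        block_mm = int((win_arr[ts:te] != read_arr[qs:qe]).sum())
        mismatches += block_mm
        matches += (te - ts) - block_mm
        cig.append((te - ts, "M"))
        prev_t, prev_q = te, qe
    tail = rl - int(q_blocks[-1][1])
    if tail:
        cig.append((tail, "S"))

    if matches / rl < identity_floor:
        return None

    # merge adjacent same-op runs
    merged: list[tuple[int, str]] = []
    for n, op in cig:
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    cigar = "".join(f"{n}{op}" for n, op in merged)
    nm = mismatches + ins_b + del_b
    pos0 = wstart + int(t_blocks[0][0])
    return pos0, cigar, nm


def emulate_alignments(
    read_set: SimulatedReadSet,
    pair: GenomePair,
    graft_path: str,
    host_path: str,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
) -> tuple[str, str]:
    """Align every read against both genomes and write two BAM/SAM files.

    Deterministic replacement for an external aligner: each read is compared
    to the homologous window of each genome (found through the ancestor
    coordinate maps). Indel-free windows take a vectorized ungapped path
    (full-length match CIGAR, NM = mismatch count); windows crossed by an
    indel, and low-identity ungapped hits, go through affine-gap alignment
    with soft-clip semantics. NM follows the SAM convention
    (mismatches + inserted + deleted bases). Reads below ``identity_floor``
    matching bases are emitted as unmapped.
    """
    rl = read_set.read_length
    n = len(read_set)
    mates = [(read_set.codes1, read_set.starts1, read_set.rev1)]
    if read_set.paired:
        mates.append((read_set.codes2, read_set.starts2, read_set.rev2))

    aligner = _make_aligner()
    out = {}
    for species, path in (("graft", graft_path), ("host", host_path)):
        target_codes = pair.genome_codes(species)
        glen = target_codes.size
        per_mate = []
        for codes, starts, rev in mates:
            # reference-forward base codes of every read
            fwd = np.where(rev[:, None], _revcomp_codes(codes), codes).astype(np.uint8)
            pos = np.full(n, -1, dtype=np.int64)
            cigars: list[Optional[str]] = [None] * n
            nms = np.zeros(n, dtype=np.int64)
            mapped = np.zeros(n, dtype=bool)

            for origin in ("graft", "host"):
                sel = np.nonzero(read_set.species == origin)[0]
                if sel.size == 0:
                    continue
                tstart, contig = _window_positions(
                    pair, origin, species, starts[sel], rl
                )
                ok = contig & (tstart >= 0) & (tstart + rl <= glen)
                fast, fast_t = sel[ok], tstart[ok]
                slow_local = sel[~ok]
                if fast.size:
                    windows = target_codes[fast_t[:, None] + np.arange(rl)]
                    mm = (windows != fwd[fast]).sum(axis=1)
                    good = (rl - mm) / rl >= identity_floor
                    gsel = fast[good]
                    mapped[gsel] = True
                    pos[gsel] = fast_t[good]
                    nms[gsel] = mm[good]
                    full = f"{rl}M"
                    for i in gsel:
                        cigars[i] = full
                    slow_local = np.concatenate([slow_local, fast[~good]])
                for i in slow_local:
                    res = _align_gapped(
                        _codes_to_str(fwd[i]), pair, origin, species,
                        int(starts[i]), rl, aligner, identity_floor,
                    )
                    if res is not None:
                        pos[i], cigars[i], nms[i] = res
                        mapped[i] = True
            per_mate.append((fwd, rev, pos, cigars, nms, mapped))
        out[species] = (path, glen, per_mate)

    for species, (path, glen, per_mate) in out.items():
        _write_emulated_bam(read_set, path, glen, per_mate)
    return graft_path, host_path


def _write_emulated_bam(read_set: SimulatedReadSet, path: str, glen: int,
                        per_mate) -> None:
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unknown"},
         "SQ": [{"SN": "synth", "LN": int(glen)}]}
    )
    mode = "w" if str(path).endswith(".sam") else "wb"
    qual = pysam.qualitystring_to_array("I" * read_set.read_length)
    with pysam.AlignmentFile(path, mode, header=header) as bam:
        for i, name in enumerate(read_set.names):
            for mate_idx, (fwd, rev, pos, cigars, nms, mapped) in enumerate(per_mate):
                seg = pysam.AlignedSegment(header)
                seg.query_name = str(name)
                flag = 0
                if read_set.paired:
                    other = per_mate[1 - mate_idx]
                    flag |= 0x1
                    flag |= 0x40 if mate_idx == 0 else 0x80
                    if not other[5][i]:
                        flag |= 0x8
                    elif other[1][i]:
                        flag |= 0x20
                if mapped[i]:
                    if rev[i]:
                        flag |= 0x10
                    seg.flag = flag
                    # SEQ reference-forward when mapped
                    seg.query_sequence = _codes_to_str(fwd[i])
                    seg.reference_id = 0
                    seg.reference_start = int(pos[i])
                    seg.cigarstring = cigars[i]
                    seg.mapping_quality = 60
                    seg.query_qualities = qual
                    seg.set_tag("NM", int(nms[i]))
                else:
                    flag |= 0x4
                    seg.flag = flag
                    codes = read_set.codes1 if mate_idx == 0 else read_set.codes2
                    seg.query_sequence = _codes_to_str(codes[i])
                    seg.reference_id = -1
                    seg.reference_start = -1
                    seg.mapping_quality = 0
                    seg.query_qualities = qual
                bam.write(seg)


# ---------------------------------------------------------------------------
# Truth-based evaluation
# ---------------------------------------------------------------------------

def run_mixing_benchmark(
    workdir: str,
    seed: int = 0,
    genome_length: int = 1_000_000,
    divergence: float = 0.08,
    conserved_fraction: float = 0.10,
    conserved_divergence: float = 0.01,
    indel_rate: float = 1e-4,
    n_per_species: int = 50_000,
    read_length: int = 100,
    paired: bool = True,
    error_rate: float = 0.01,
    graft_fraction: float = 0.5,
    params=None,
):
    """In-silico mixing experiment: simulate, align, filter, evaluate.

    Evolves a genome pair, simulates ``n_per_species`` reads (pairs) from
    each genome, mixes them at ``graft_fraction``, emulates alignments to
    both genomes, runs the edit-distance filter, and scores the output
    against the truth. Returns ``(EvaluationResult, FilterReport)``.
    Deterministic for a given seed; intermediate BAMs land in ``workdir``.
    """
    import os

    from .classifier import FilterParams
    from .filter_pipeline import SampleSpec, run_filter

    params = params or FilterParams(emit_host_output=True)
    pair = evolve_pair(
        genome_length, divergence, conserved_fraction, conserved_divergence,
        indel_rate, seed=seed,
    )
    kw = dict(read_length=read_length, paired=paired, error_rate=error_rate)
    graft_reads = simulate_reads(pair.graft_genome, n_per_species,
                                 seed=seed + 1, species="graft", **kw)
    host_reads = simulate_reads(pair.host_genome, n_per_species,
                                seed=seed + 2, species="host", **kw)
    total = n_per_species * 2 if graft_fraction == 0.5 else int(
        round(min(n_per_species / max(graft_fraction, 1 - graft_fraction),
                  2 * n_per_species))
    )
    mix = mix_read_sets(graft_reads, host_reads, graft_fraction, total, seed=seed + 3)

    graft_bam = os.path.join(workdir, "mix_graft_aligned.bam")
    host_bam = os.path.join(workdir, "mix_host_aligned.bam")
    emulate_alignments(mix, pair, graft_bam, host_bam)
    sample = SampleSpec(
        graft_bam=graft_bam,
        host_bam=host_bam,
        graft_out=os.path.join(workdir, "mix_filtered_graft.bam"),
        host_out=os.path.join(workdir, "mix_filtered_host.bam"),
        sample_id="insilico_mix",
    )
    report = run_filter(sample, params)
    result = evaluate_classification(
        mix, sample.graft_out,
        sample.host_out if params.emit_host_output else None, report,
    )
    return result, report


@dataclass
class EvaluationResult:
    """Confusion of truth species vs output assignment, plus headline rates."""

    confusion: Dict[str, Dict[str, int]]
    host_removal_pct: float
    graft_retention_pct: float

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion,
            "host_removal_pct": self.host_removal_pct,
            "graft_retention_pct": self.graft_retention_pct,
        }


def _bam_names(path: Optional[str]) -> set:
    if path is None:
        return set()
    with pysam.AlignmentFile(path, check_sq=False) as bam:
        return {seg.query_name for seg in bam}


def evaluate_classification(
    truth: Dict[str, tuple] | SimulatedReadSet,
    graft_out_bam: str,
    host_out_bam: Optional[str] = None,
    report=None,
) -> EvaluationResult:
    """Score filter outputs against ground truth.

    ``host_removal_pct`` is the percentage of truth-host reads absent from
    the graft output; ``graft_retention_pct`` the percentage of truth-graft
    reads present in it. Every output name must exist in the truth table.
    """
    if isinstance(truth, SimulatedReadSet):
        truth = truth.truth()
    graft_names = _bam_names(graft_out_bam)
    host_names = _bam_names(host_out_bam)
    unknown = (graft_names | host_names) - set(truth)
    if unknown:
        raise ValueError(
            f"{len(unknown)} output read names missing from truth "
            f"(e.g. {sorted(unknown)[:3]})"
        )

    confusion = {
        sp: {"in_graft_output": 0, "in_host_output": 0, "unassigned": 0}
        for sp in ("graft", "host")
    }
    for name, rec in truth.items():
        sp = rec[0] if isinstance(rec, (tuple, list)) else str(rec)
        if name in graft_names:
            confusion[sp]["in_graft_output"] += 1
        elif name in host_names:
            confusion[sp]["in_host_output"] += 1
        else:
            confusion[sp]["unassigned"] += 1

    n_host = sum(confusion["host"].values())
    n_graft = sum(confusion["graft"].values())
    host_removal = (
        100.0 * (n_host - confusion["host"]["in_graft_output"]) / n_host
        if n_host else 100.0
    )
    graft_retention = (
        100.0 * confusion["graft"]["in_graft_output"] / n_graft if n_graft else 100.0
    )
    if report is not None:
        total_out = len(graft_names)
        if report.counts.get("GRAFT", 0) != total_out:
            raise ValueError(
                "filter report GRAFT count disagrees with graft output BAM"
            )
    return EvaluationResult(
        confusion=confusion,
        host_removal_pct=host_removal,
        graft_retention_pct=graft_retention,
    )
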