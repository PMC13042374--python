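"""Seeded synthetic cohorts with ground truth for every pipeline stage.

The generator builds a toy genome (random sequence at a configured GC
content, regularly spaced genes, a jittered nucleosome-center track) and
then emits cfDNA-like samples.  Each sample receives somatic variants
drawn from a trinucleotide-context model: controls draw from a smooth
"background" profile (standing in for platform noise plus clonal
hematopoiesis), cancer samples additionally draw variants from a
configured mixture of peaked, COSMIC-like signature columns so that the
expected tumor share of all variants equals ``tumor_fraction``.

Fragments covering a variant locus carry the variant allele with the
locus' allele fraction; allele-conditional effects are applied at the
fragment-sampling level, not post hoc on summaries:

* Mut fragments draw lengths from the wild-type size mixture shifted by
  ``size_shift`` (scaled by origin: clonal-hematopoiesis variants get
  ``ch_effect_scale`` of the full tumor effect);
* placements producing CCCA end motifs or CTCC breakpoint motifs are
  down-weighted for Mut fragments (motif depletion);
* Mut ends are preferentially placed within ±50 bp of nucleosome
  centers (nucleosome enrichment);
* per-CpG methylation probabilities are reduced by
  ``methylation_shift`` percentage points for Mut fragments.

All fragments share a deterministic per-position cleavage-preference
track, so a healthy panel's end model is informative about wild-type
ends.  Sequencing errors flip observed bases at rate ``error_rate`` and
sprinkle extra mismatched base calls along fragments; every injected
variant and every simulated error site is recorded in the truth
manifest.  Everything derives from one master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import FragmentRecord, Gene, GenomicInterval, ReferenceGenome
from .fragmentomics import NUCLEOSOME_HALF_WINDOW
from .signatures import CONTEXT_96, SUBSTITUTIONS, SignaturePool
from .variants import VariantCall

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"
_FLANKS = ("A", "C", "G", "T")
_EDGE_MARGIN = 300  # keep variants and fragments away from contig edges


@dataclass
class SizeMixture:
    """Gaussian mixture of fragment lengths (bp)."""

    means: tuple[float, ...] = (166.0, 140.0)
    sds: tuple[float, ...] = (9.0, 12.0)
    weights: tuple[float, ...] = (0.88, 0.12)

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("mixture weights must sum to 1")

    def sample(self, rng: np.random.Generator, n: int, shift: float = 0.0) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=self.weights)
        lengths = rng.normal(
            np.asarray(self.means)[comp] + shift, np.asarray(self.sds)[comp]
        )
        return np.maximum(np.rint(lengths).astype(np.int64), 60)

    def frac_short(self, max_length: int = 150, shift: float = 0.0) -> float:
        """Analytic P(round(length) <= max_length) via the mixture CDF."""
        return float(
            sum(
                w * stats.norm.cdf(max_length + 0.5, loc=m + shift, scale=s)
                for w, m, s in zip(self.weights, self.means, self.sds)
            )
        )


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort."""

    # genome
    n_chroms: int = 2
    chrom_length: int = 400_000
    gc_content: float = 0.45
    gene_length: int = 4_000
    gene_spacing: int = 15_000
    nucleosome_spacing: int = 185
    nucleosome_jitter: int = 18
    # cohort
    n_controls: int = 30
    n_cancers: int = 30
    tumor_fraction: float = 0.2
    background_rate: float = 2.5e-4  # variants per bp per sample
    signature_mixture: dict[str, float] = field(
        default_factory=lambda: {"SIG1": 0.5, "SIG2": 0.3, "SIG3": 0.2}
    )
    depth_per_locus: float = 10.0
    vaf_range: tuple[float, float] = (0.12, 0.35)
    error_rate: float = 1e-3
    size_mixture: SizeMixture = field(default_factory=SizeMixture)
    # allele-conditional (Mut) effects; tumor-origin fragments get the full
    # effect, clonal-hematopoiesis/background ones ch_effect_scale of it
    size_shift: float = -20.0
    ccca_depletion: float = 0.5
    ctcc_depletion: float = 0.5
    nucleosome_enrichment: float = 0.8
    methylation_shift: float = -5.0  # percentage points
    ch_effect_scale: float = 0.5
    # baseline biology
    methylation_base: dict[str, float] = field(
        default_factory=lambda: {"promoter": 0.15, "gene_body": 0.80, "intergenic": 0.70}
    )
    nucleosome_end_weight: float = 0.6  # baseline weight of within-nucleosome ends
    cut_hotspot_fraction: float = 0.05
    cut_hotspot_weight: float = 5.0
    # panel
    n_panel_fragments: int = 10_000
    master_seed: int = 7

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction < 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1)")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if not np.isclose(sum(self.signature_mixture.values()), 1.0):
            raise ValueError("signature mixture weights must sum to 1")
        if self.chrom_length < 4 * self.nucleosome_spacing:
            raise ValueError("genome too short for the nucleosome spacing")

    def effect_scale(self, origin: str) -> float:
        return 1.0 if origin == "tumor" else self.ch_effect_scale

    def expected_diff_size(self, label: str) -> float:
        """Analytic Mut-minus-Wt short-fragment fraction for a sample class.

        Cancer Mut pools mix background (scaled effect) and tumor (full
        effect) origins at the configured tumor fraction.
        """
        wt = self.size_mixture.frac_short()
        mut_ch = self.size_mixture.frac_short(shift=self.size_shift * self.ch_effect_scale)
        if label == "control":
            return mut_ch - wt
        mut_tumor = self.size_mixture.frac_short(shift=self.size_shift)
        f = self.tumor_fraction
        return (1 - f) * mut_ch + f * mut_tumor - wt

    def expected_diff_methylation(self, label: str, region: str = "gene_body") -> float:
        """Analytic Mut-minus-Wt methylation density (percentage points)."""
        scale_ch = self.ch_effect_scale
        if label == "control":
            return self.methylation_shift * scale_ch
        f = self.tumor_fraction
        return self.methylation_shift * ((1 - f) * scale_ch + f)


# ---------------------------------------------------------------------------
# signature pool
# ---------------------------------------------------------------------------

def toy_signature_pool(n_signatures: int = 8, seed: int = 0,
                       peak_channels: int = 4, peak_mass: float = 0.75) -> SignaturePool:
    """A small synthetic pool of sharply peaked, COSMIC-like columns.

    Each column concentrates ``peak_mass`` on a few random channels and
    spreads the rest uniformly; real COSMIC matrices in the same TSV
    layout are drop-in replacements.
    """
    rng = np.random.default_rng(seed)
    columns = np.zeros((96, n_signatures))
    for j in range(n_signatures):
        peaks = rng.choice(96, size=peak_channels, replace=False)
        peak_weights = rng.dirichlet(np.ones(peak_channels)) * peak_mass
        columns[:, j] = (1.0 - peak_mass) / 96.0
        columns[peaks, j] += peak_weights
    names = [f"SIG{j + 1}" for j in range(n_signatures)]
    return SignaturePool(columns, names)


def background_profile(seed: int, concentration: float = 60.0) -> np.ndarray:
    """Smooth 96-channel noise profile shared by all samples of a cohort."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(96, concentration))


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

def simulate_reference(
    config: SimConfig,
) -> tuple[ReferenceGenome, dict[str, np.ndarray]]:
    """Toy genome + gene annotation + jittered nucleosome-center track."""
    seq_seed, nuc_seed = np.random.SeedSequence(config.master_seed).spawn(2)
    rng = np.random.default_rng(seq_seed)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    sequences: dict[str, str] = {}
    genes: list[Gene] = []
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        codes = rng.choice(4, size=config.chrom_length, p=probs)
        sequences[chrom] = "".join(_CODE_BASE[i] for i in codes)
        pos = _EDGE_MARGIN + config.gene_spacing // 2
        g = 0
        while pos + config.gene_length < config.chrom_length - _EDGE_MARGIN:
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(chrom, pos, pos + config.gene_length, strand,
                              f"{chrom}_g{g}"))
            pos += config.gene_spacing + int(rng.integers(-2000, 2000))
            g += 1
    reference = ReferenceGenome(sequences, genes)

    nuc_rng = np.random.default_rng(nuc_seed)
    centers: dict[str, np.ndarray] = {}
    for chrom in sequences:
        grid = np.arange(
            config.nucleosome_spacing,
            config.chrom_length - config.nucleosome_spacing,
            config.nucleosome_spacing,
            dtype=np.int64,
        )
        jitter = nuc_rng.integers(
            -config.nucleosome_jitter, config.nucleosome_jitter + 1, size=len(grid)
        )
        centers[chrom] = np.sort(grid + jitter)
    return reference, centers


# ---------------------------------------------------------------------------
# workspace: precomputed per-chromosome tracks
# ---------------------------------------------------------------------------

class _Workspace:
    """Precomputed motif/nucleosome/cleavage tracks and context pools."""

    def __init__(self, config: SimConfig, reference: ReferenceGenome,
                 centers: dict[str, np.ndarray]) -> None:
        self.config = config
        self.reference = reference
        self.centers = centers
        self.chroms = sorted(reference.sequences)
        self.u_ccca: dict[str, np.ndarray] = {}
        self.d_ccca: dict[str, np.ndarray] = {}
        self.u_ctcc: dict[str, np.ndarray] = {}
        self.d_ctcc: dict[str, np.ndarray] = {}
        self.near_nuc: dict[str, np.ndarray] = {}
        self.cut_pref: dict[str, np.ndarray] = {}
        self.cpgs: dict[str, np.ndarray] = {}
        cut_rng = np.random.default_rng(
            np.random.SeedSequence([config.master_seed, 0xC1EA]).generate_state(1)[0]
        )
        for chrom in self.chroms:
            seq = reference.sequences[chrom]
            codes = np.frombuffer(seq.encode(), dtype=np.uint8)
            n = len(codes)
            a, c, g, t = (codes == ord(b) for b in "ACGT")

            def match(pattern: str, offset: int) -> np.ndarray:
                """mask[p] = seq[p+offset : p+offset+4] == pattern."""
                mask = np.zeros(n, dtype=bool)
                lo, hi = -offset, n - offset - 4
                window = np.ones(hi - lo, dtype=bool)
                base_masks = {"A": a, "C": c, "G": g, "T": t}
                for k, ch in enumerate(pattern):
                    window &= base_masks[ch][lo + offset + k: hi + offset + k]
                mask[lo:hi] = window
                return mask

            self.u_ccca[chrom] = match("CCCA", 0)
            self.d_ccca[chrom] = match("TGGG", -3)  # revcomp == CCCA
            self.u_ctcc[chrom] = match("CTCC", -2)
            self.d_ctcc[chrom] = match("GGAG", -1)  # revcomp == CTCC

            near = np.zeros(n + 1, dtype=np.int64)
            for center in centers[chrom]:
                lo = max(0, int(center) - NUCLEOSOME_HALF_WINDOW)
                hi = min(n, int(center) + NUCLEOSOME_HALF_WINDOW + 1)
                near[lo] += 1
                near[hi] -= 1
            self.near_nuc[chrom] = np.cumsum(near[:-1]) > 0

            hot = cut_rng.random(n) < config.cut_hotspot_fraction
            pref = np.ones(n)
            pref[hot] = config.cut_hotspot_weight
            self.cut_pref[chrom] = pref

            self.cpgs[chrom] = np.flatnonzero(c[:-1] & g[1:]).astype(np.int64)

        self._build_context_pools()

    def _build_context_pools(self) -> None:
        """Position pools per pyrimidine trinucleotide context.

        Purine-centered positions enter through their reverse complement
        with strand flag -1; sampling then records the forward-strand
        ref/alt pair.
        """
        pools: dict[int, list[np.ndarray]] = {}
        self.context_pools: dict[int, np.ndarray] = {}
        for ci, chrom in enumerate(self.chroms):
            seq = self.reference.sequences[chrom]
            codes = np.array([_BASE_CODE.get(b, -1) for b in seq], dtype=np.int64)
            valid = codes >= 0
            n = len(codes)
            left, mid, right = codes[:-2], codes[1:-1], codes[2:]
            ok = valid[:-2] & valid[1:-1] & valid[2:]
            pos = np.arange(1, n - 1)
            margin_ok = (pos >= _EDGE_MARGIN) & (pos < n - _EDGE_MARGIN)
            ok &= margin_ok
            pyr = ok & ((mid == 1) | (mid == 3))  # C or T
            pur = ok & ((mid == 0) | (mid == 2))  # A or G
            fwd_code = 16 * left + 4 * mid + right
            rc_code = 16 * (3 - right) + 4 * (3 - mid) + (3 - left)
            for mask, code_arr, strand in ((pyr, fwd_code, 1), (pur, rc_code, -1)):
                sel = np.flatnonzero(mask)
                for code in np.unique(code_arr[sel]):
                    idx = sel[code_arr[sel] == code]
                    entry = np.column_stack(
                        [np.full(len(idx), ci), pos[idx], np.full(len(idx), strand)]
                    )
                    pools.setdefault(int(code), []).append(entry)
        for code, blocks in pools.items():
            self.context_pools[code] = np.vstack(blocks)

    def sample_channel_position(
        self, channel: int, rng: np.random.Generator, taken: set[tuple[str, int]]
    ) -> Optional[tuple[str, int, str, str]]:
        """Draw (chrom, pos0, ref, alt) for a 96-channel index."""
        sub = SUBSTITUTIONS[channel // 16]
        five = _FLANKS[(channel % 16) // 4]
        three = _FLANKS[channel % 4]
        pyr, alt = sub.split(">")
        code = 16 * _BASE_CODE[five] + 4 * _BASE_CODE[pyr] + _BASE_CODE[three]
        pool = self.context_pools.get(code)
        if pool is None or len(pool) == 0:
            return None
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(20):
            ci, pos, strand = pool[rng.integers(len(pool))]
            chrom = self.chroms[int(ci)]
            key = (chrom, int(pos))
            near = any((chrom, p) in taken for p in range(int(pos) - 2, int(pos) + 3))
            if near:
                continue
            if strand == 1:
                return chrom, int(pos), pyr, alt
            return chrom, int(pos), comp[pyr], comp[alt]
        return None


# ---------------------------------------------------------------------------
# fragment sampling
# ---------------------------------------------------------------------------

def _place_fragment(
    ws: _Workspace,
    chrom: str,
    locus: int,
    length: int,
    rng: np.random.Generator,
    ccca_factor: float,
    ctcc_factor: float,
    nuc_multiplier: float,
) -> Optional[int]:
    """Choose a fragment start covering ``locus``, weighted by the
    cleavage-preference, motif, and nucleosome tracks at both termini."""
    n = ws.reference.chrom_length(chrom)
    lo = max(locus - length + 1, 4)
    hi = min(locus, n - length - 4)
    if hi < lo:
        return None
    u = np.arange(lo, hi + 1)
    d = u + length - 1
    w = ws.cut_pref[chrom][u] * ws.cut_pref[chrom][d]
    if ccca_factor != 1.0:
        w *= np.where(ws.u_ccca[chrom][u], ccca_factor, 1.0)
        w *= np.where(ws.d_ccca[chrom][d], ccca_factor, 1.0)
    if ctcc_factor != 1.0:
        w *= np.where(ws.u_ctcc[chrom][u], ctcc_factor, 1.0)
        w *= np.where(ws.d_ctcc[chrom][d], ctcc_factor, 1.0)
    base_in = ws.config.nucleosome_end_weight
    nuc_w = np.where(ws.near_nuc[chrom][u], base_in * nuc_multiplier, 1.0)
    nuc_w = nuc_w * np.where(ws.near_nuc[chrom][d], base_in * nuc_multiplier, 1.0)
    w *= nuc_w
    total = w.sum()
    if total <= 0:
        return None
    return int(rng.choice(u, p=w / total))


def _methylate(
    ws: _Workspace,
    classifier,
    chrom: str,
    start: int,
    end: int,
    rng: np.random.Generator,
    shift_points: float,
) -> list[tuple[int, bool]]:
    cpgs = ws.cpgs[chrom]
    lo = int(np.searchsorted(cpgs, start))
    hi = int(np.searchsorted(cpgs, end - 1))
    calls = []
    for pos in cpgs[lo:hi]:
        region = classifier.classify(chrom, int(pos))
        p = np.clip(ws.config.methylation_base[region] + shift_points / 100.0, 0.0, 1.0)
        calls.append((int(pos), bool(rng.random() < p)))
    return calls


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SimSample:
    """One synthetic sample with its per-sample ground truth."""

    sample_id: str
    label: str  # control | cancer
    tumor_fraction: float
    fragments: list[FragmentRecord]
    variants: list[dict]  # chrom, pos (1-based), ref, alt, vaf, origin
    error_sites: list[dict]  # chrom, pos (1-based), base
    fragment_truth: dict[str, dict]  # name -> {allele, origin}

    def truth_calls(self) -> list[VariantCall]:
        """Injected variants as VariantCall records (for oracle checks)."""
        out = []
        for v in self.variants:
            out.append(VariantCall(v["chrom"], v["pos"], ref=v["ref"], alt=v["alt"],
                                   qual=255.0, depth=1, alt_count=1,
                                   origin_class=v["origin"]))
        return out


def _generate_sample(
    config: SimConfig,
    ws: _Workspace,
    classifier,
    pool: SignaturePool,
    bg_profile: np.ndarray,
    rng: np.random.Generator,
    sample_id: str,
    label: str,
    tumor_fraction: float,
) -> SimSample:
    genome_len = config.n_chroms * config.chrom_length
    bg_lam = config.background_rate * genome_len
    f = tumor_fraction
    tumor_lam = bg_lam * f / (1.0 - f)
    n_background = int(rng.poisson(bg_lam))
    n_tumor = int(rng.poisson(tumor_lam))

    sig_names = list(config.signature_mixture)
    sig_weights = np.array([config.signature_mixture[s] for s in sig_names])
    name_to_col = {n: i for i, n in enumerate(pool.names)}
    for name in sig_names:
        if name not in name_to_col:
            raise ValueError(f"signature {name!r} not present in the pool")

    taken: set[tuple[str, int]] = set()
    variants: list[dict] = []
    for origin, count in (("background", n_background), ("tumor", n_tumor)):
        for _ in range(count):
            if origin == "background":
                channel = int(rng.choice(96, p=bg_profile))
            else:
                sig = sig_names[int(rng.choice(len(sig_names), p=sig_weights))]
                channel = int(rng.choice(96, p=pool.matrix[:, name_to_col[sig]]))
            drawn = ws.sample_channel_position(channel, rng, taken)
            if drawn is None:
                continue
            chrom, pos0, ref, alt = drawn
            taken.add((chrom, pos0))
            vaf = float(rng.uniform(*config.vaf_range))
            variants.append(
                {"chrom": chrom, "pos": pos0 + 1, "ref": ref, "alt": alt,
                 "vaf": vaf, "origin": origin}
            )

    fragments: list[FragmentRecord] = []
    fragment_truth: dict[str, dict] = {}
    error_sites: list[dict] = []
    frag_no = 0
    for variant in variants:
        chrom, pos0 = variant["chrom"], variant["pos"] - 1
        depth = int(rng.poisson(config.depth_per_locus))
        for _ in range(depth):
            carries_alt = rng.random() < variant["vaf"]
            scale = config.effect_scale(variant["origin"]) if carries_alt else 0.0
            shift = config.size_shift * scale
            length = int(config.size_mixture.sample(rng, 1, shift=shift)[0])
            start = _place_fragment(
                ws, chrom, pos0, length, rng,
                ccca_factor=1.0 - config.ccca_depletion * scale,
                ctcc_factor=1.0 - config.ctcc_depletion * scale,
                nuc_multiplier=1.0 + config.nucleosome_enrichment * scale,
            )
            if start is None:
                continue
            name = f"{sample_id}_f{frag_no}"
            frag_no += 1
            true_base = variant["alt"] if carries_alt else variant["ref"]
            observed = true_base
            if rng.random() < config.error_rate:
                others = [b for b in "ACGT" if b != true_base]
                observed = others[int(rng.integers(3))]
                error_sites.append({"chrom": chrom, "pos": pos0 + 1, "base": observed})
            base_calls = [(pos0, observed, 37)]
            # stray errors elsewhere on the fragment
            n_extra = int(rng.poisson(config.error_rate * (length - 1)))
            for _ in range(n_extra):
                epos = start + int(rng.integers(length))
                if epos == pos0:
                    continue
                ref_base = ws.reference.base(chrom, epos)
                if ref_base == "N":
                    continue
                others = [b for b in "ACGT" if b != ref_base]
                ebase = others[int(rng.integers(3))]
                base_calls.append((epos, ebase, 37))
                error_sites.append({"chrom": chrom, "pos": epos + 1, "base": ebase})
            meth = _methylate(ws, classifier, chrom, start, start + length, rng,
                              config.methylation_shift * scale)
            fragments.append(
                FragmentRecord(
                    GenomicInterval(chrom, start, start + length),
                    name=name, mapq=60, base_calls=base_calls, meth_calls=meth,
                )
            )
            fragment_truth[name] = {
                "allele": "alt" if carries_alt else "ref",
                "origin": variant["origin"] if carries_alt else None,
            }
    return SimSample(sample_id, label, tumor_fraction, fragments, variants,
                     error_sites, fragment_truth)


def simulate_cohort(
    config: SimConfig,
    reference: ReferenceGenome,
    centers: dict[str, np.ndarray],
    pool: Optional[SignaturePool] = None,
) -> tuple[list[SimSample], dict]:
    """Generate the full cohort plus its truth manifest."""
    from .methylation import RegionClassifier

    ws = _Workspace(config, reference, centers)
    classifier = RegionClassifier(reference.genes)
    if pool is None:
        pool = toy_signature_pool(seed=config.master_seed)
    seeds = np.random.SeedSequence([config.master_seed, 0xC007]).spawn(
        config.n_controls + config.n_cancers + 1
    )
    bg_profile = background_profile(
        int(seeds[-1].generate_state(1)[0] % (2**31 - 1))
    )
    samples: list[SimSample] = []
    idx = 0
    for i in range(config.n_controls):
        rng = np.random.default_rng(seeds[idx]); idx += 1
        samples.append(_generate_sample(
            config, ws, classifier, pool, bg_profile, rng,
            f"control_{i:03d}", "control", 0.0,
        ))
    for i in range(config.n_cancers):
        rng = np.random.default_rng(seeds[idx]); idx += 1
        samples.append(_generate_sample(
            config, ws, classifier, pool, bg_profile, rng,
            f"cancer_{i:03d}", "cancer", config.tumor_fraction,
        ))
    manifest = {
        "config": _config_dict(config),
        "samples": [
            {
                "sample_id": s.sample_id,
                "label": s.label,
                "tumor_fraction": s.tumor_fraction,
                "n_fragments": len(s.fragments),
                "variants": s.variants,
                "n_error_sites": len(s.error_sites),
            }
            for s in samples
        ],
    }
    return samples, manifest


def simulate_panel(
    config: SimConfig,
    reference: ReferenceGenome,
    centers: dict[str, np.ndarray],
    n_fragments: Optional[int] = None,
) -> list[FragmentRecord]:
    """Healthy-panel fragments (wild-type placement law, disjoint stream)."""
    ws = _Workspace(config, reference, centers)
    return _panel_fragments(config, ws, n_fragments)


def _panel_fragments(
    config: SimConfig, ws: _Workspace, n_fragments: Optional[int] = None
) -> list[FragmentRecord]:
    n_fragments = n_fragments or config.n_panel_fragments
    rng = np.random.default_rng(
        np.random.SeedSequence([config.master_seed, 0xAE1]).generate_state(1)[0]
    )
    chrom_lengths = np.array([ws.reference.chrom_length(c) for c in ws.chroms], dtype=float)
    chrom_p = chrom_lengths / chrom_lengths.sum()
    base_in = config.nucleosome_end_weight
    fragments: list[FragmentRecord] = []
    max_w = config.cut_hotspot_weight ** 2
    i = 0
    while len(fragments) < n_fragments:
        # batched rejection sampling against the placement weight tracks
        batch = max(2 * (n_fragments - len(fragments)), 1000)
        chrom_idx = rng.choice(len(ws.chroms), size=batch, p=chrom_p)
        lengths = config.size_mixture.sample(rng, batch)
        accept_u = rng.random(batch)
        for ci in range(len(ws.chroms)):
            chrom = ws.chroms[ci]
            sel = np.flatnonzero(chrom_idx == ci)
            if len(sel) == 0:
                continue
            n = ws.reference.chrom_length(chrom)
            ls = lengths[sel]
            starts = rng.integers(4, n - ls - 4)
            ends = starts + ls - 1
            w = ws.cut_pref[chrom][starts] * ws.cut_pref[chrom][ends]
            w = w * np.where(ws.near_nuc[chrom][starts], base_in, 1.0)
            w = w * np.where(ws.near_nuc[chrom][ends], base_in, 1.0)
            ok = accept_u[sel] * max_w <= w
            for start, length in zip(starts[ok], ls[ok]):
                if len(fragments) >= n_fragments:
                    break
                fragments.append(
                    FragmentRecord(
                        GenomicInterval(chrom, int(start), int(start + length)),
                        name=f"panel_f{i}", mapq=60)
                )
                i += 1
    return fragments


# ---------------------------------------------------------------------------
# fragment-free variant sets (signature-level studies)
# ---------------------------------------------------------------------------

def simulate_variant_sets(
    config: SimConfig,
    reference: ReferenceGenome,
    centers: dict[str, np.ndarray],
    n_controls: Optional[int] = None,
    n_cancers: Optional[int] = None,
    tumor_fraction: Optional[float] = None,
    pool: Optional[SignaturePool] = None,
    seed_tag: int = 0,
) -> list[tuple[str, str, list[VariantCall]]]:
    """Variant call sets drawn from the channel model, without fragments.

    A light path for studies that only exercise mutation profiles and
    deconvolution; returns (sample_id, label, calls) triples.
    """
    ws = _Workspace(config, reference, centers)
    if pool is None:
        pool = toy_signature_pool(seed=config.master_seed)
    n_controls = config.n_controls if n_controls is None else n_controls
    n_cancers = config.n_cancers if n_cancers is None else n_cancers
    f = config.tumor_fraction if tumor_fraction is None else tumor_fraction
    seeds = np.random.SeedSequence(
        [config.master_seed, 0x5E7, seed_tag]
    ).spawn(n_controls + n_cancers + 1)
    bg_profile = background_profile(int(seeds[-1].generate_state(1)[0] % (2**31 - 1)))

    sig_names = list(config.signature_mixture)
    sig_weights = np.array([config.signature_mixture[s] for s in sig_names])
    name_to_col = {n: i for i, n in enumerate(pool.names)}

    out = []
    genome_len = config.n_chroms * config.chrom_length
    bg_lam = config.background_rate * genome_len
    for k in range(n_controls + n_cancers):
        label = "control" if k < n_controls else "cancer"
        frac = 0.0 if label == "control" else f
        rng = np.random.default_rng(seeds[k])
        n_bg = int(rng.poisson(bg_lam))
        n_tm = int(rng.poisson(bg_lam * frac / (1 - frac)))
        taken: set[tuple[str, int]] = set()
        calls: list[VariantCall] = []
        for origin, count in (("background", n_bg), ("tumor", n_tm)):
            for _ in range(count):
                if origin == "background":
                    channel = int(rng.choice(96, p=bg_profile))
                else:
                    sig = sig_names[int(rng.choice(len(sig_names), p=sig_weights))]
                    channel = int(rng.choice(96, p=pool.matrix[:, name_to_col[sig]]))
                drawn = ws.sample_channel_position(channel, rng, taken)
                if drawn is None:
                    continue
                chrom, pos0, ref, alt = drawn
                taken.add((chrom, pos0))
                calls.append(VariantCall(chrom, pos0 + 1, ref=ref, alt=alt,
                                         qual=255.0, depth=30, alt_count=5,
                                         origin_class=origin))
        sid = f"{label}_{k:03d}"
        out.append((sid, label, calls))
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["size_mixture"] = asdict(config.size_mixture)
    return d


def write_cohort(
    out_dir: str | Path,
    reference: ReferenceGenome,
    centers: dict[str, np.ndarray],
    samples: Sequence[SimSample],
    manifest: dict,
) -> None:
    """Write FASTA, annotation, nucleosome BED, per-sample fragment BED +
    sidecars, and the JSON truth manifest."""
    from . import io as io_mod

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.fa", "w") as handle:
        for chrom in sorted(reference.sequences):
            handle.write(f">{chrom}\n")
            seq = reference.sequences[chrom]
            for i in range(0, len(seq), 80):
                handle.write(seq[i: i + 80] + "\n")
    io_mod.write_genes(out / "genes.tsv", reference.genes)
    io_mod.write_nucleosome_centers(out / "nucleosomes.bed", centers)
    for sample in samples:
        io_mod.write_fragments(out / f"{sample.sample_id}.fragments.bed",
                               sample.fragments)
        io_mod.write_base_call_sidecar(out / f"{sample.sample_id}.calls.tsv",
                                       sample.fragments)
        io_mod.write_meth_sidecar(out / f"{sample.sample_id}.meth.tsv",
                                  sample.fragments)
    with open(out / "truth.json", "w") as handle:
        json.dump(manifest, handle, indent=1)
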