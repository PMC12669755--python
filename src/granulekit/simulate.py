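"""Ground-truth-bearing synthetic data generators.

Every analysis stage in this package can be exercised offline against
simulated inputs whose generating parameters are known exactly:

* two-channel confocal stacks of germ-cell nuclei ringed by perinuclear
  granules, with a controllable true granule/cytoplasm enrichment ratio
  in the query channel (:func:`generate_granule_image`);
* two-phase in vitro condensate images with a known dense/dilute
  partition ratio (:func:`generate_condensate_image`);
* IP/input small-RNA count libraries with negative-binomial noise,
  planted Argonaute targets and positionally biased per-gene coverage
  (:func:`generate_srna_experiment`);
* protein sequences with planted glycine-rich, FG-dipeptide-dense
  segments (:func:`generate_fg_sequences`).

All generators are pure functions of ``(spec, seed)``: identical inputs
give bit-identical outputs. Noise is Poisson shot noise on expected
photon counts followed by additive Gaussian read noise for images, and
negative-binomial/multinomial sampling for count data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .images import ImageStack
from .targets import CountExperiment, CoverageSet

__all__ = [
    "GranuleImageSpec",
    "GranuleImageTruth",
    "SrnaExperimentSpec",
    "FgSequenceSpec",
    "generate_granule_image",
    "generate_condensate_image",
    "default_condensate_rois",
    "generate_srna_experiment",
    "generate_fg_sequences",
]


class InvalidSpecError(ValueError):
    """A generator spec violates its invariants."""


class GeometryError(ValueError):
    """Requested image geometry cannot be realized."""


# ---------------------------------------------------------------------------
# granule images
# ---------------------------------------------------------------------------

@dataclass
class GranuleImageSpec:
    """Parameters of a synthetic perinuclear-granule stack.

    The query channel is flat at ``cytoplasm_level`` throughout the
    cytoplasm and elevated to ``query_enrichment_ratio x cytoplasm_level``
    on the true granule mask, so the planted enrichment ratio is exact
    in expectation. The marker channel carries Gaussian puncta used for
    segmentation. Defaults mirror a pachytene-region confocal
    acquisition: 54 planes at 0.1 um steps, 0.1 um pixels.
    """

    n_nuclei: int = 4
    nucleus_radius_um: float = 2.0
    granules_per_nucleus: int = 6
    granule_sigma_um: float = 0.25
    marker_granule_intensity: float = 300.0
    query_enrichment_ratio: float = 3.0
    cytoplasm_level: float = 100.0
    noise_model: dict = field(
        default_factory=lambda: {"poisson_scale": 1.0, "gaussian_sd": 2.0}
    )
    n_planes: int = 54
    plane_spacing_um: float = 0.1
    pixel_size_um: float = 0.1
    nuclear_query_fraction: float = 0.3
    marker_background: float = 10.0

    def validate(self) -> None:
        if self.n_nuclei < 1 or self.granules_per_nucleus < 0:
            raise InvalidSpecError("counts must be positive")
        if self.n_planes < 1:
            raise InvalidSpecError("n_planes must be >= 1")
        for name in ("nucleus_radius_um", "granule_sigma_um",
                     "plane_spacing_um", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be > 0")
        if self.query_enrichment_ratio < 0:
            raise InvalidSpecError("query_enrichment_ratio must be >= 0")
        if self.cytoplasm_level <= 0:
            raise InvalidSpecError("cytoplasm_level must be > 0")
        # granule footprint (2 sigma) must fit on the rim without
        # swallowing the whole nucleus
        if 2 * self.granule_sigma_um >= self.nucleus_radius_um:
            raise GeometryError(
                "granule footprint (2 sigma) exceeds the nucleus radius; "
                "granules cannot sit on the rim"
            )


@dataclass
class GranuleImageTruth:
    """Ground truth accompanying a synthetic granule stack."""

    nucleus_masks: np.ndarray  # int labels, 0 = background
    granule_centers: list[tuple[float, float, float]]  # (z, y, x) in um
    granule_mask: np.ndarray  # bool volume
    true_ratio: float

    @property
    def cytoplasm_mask(self) -> np.ndarray:
        """Everything outside nuclei and outside the granule mask."""
        return (self.nucleus_masks == 0) & ~self.granule_mask


def _apply_noise(expected: np.ndarray, noise: dict, rng: np.random.Generator) -> np.ndarray:
    out = expected.astype(float)
    scale = float(noise.get("poisson_scale", 0.0))
    if scale > 0:
        out = rng.poisson(out * scale).astype(float) / scale
    sd = float(noise.get("gaussian_sd", 0.0))
    if sd > 0:
        out = out + rng.normal(0.0, sd, size=out.shape)
    return np.clip(out, 0.0, None)


def generate_granule_image(
    spec: GranuleImageSpec, seed: int
) -> tuple[ImageStack, GranuleImageTruth]:
    """Render a two-channel stack of nuclei ringed by perinuclear granules.

    Nuclei are spheres placed on a jittered grid; granule centres are
    sampled uniformly on each nucleus' rim circle in its equatorial
    plane. The true granule mask is the union of spheres of radius
    ``2 x granule_sigma_um`` around the centres, clipped to outside the
    nuclei (granules are cytoplasmic).

    Returns the noisy stack (channels ``marker``, ``query``) and the
    ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    px = spec.pixel_size_um
    dz = spec.plane_spacing_um
    r_nuc = spec.nucleus_radius_um / px
    r_gran_um = 2.0 * spec.granule_sigma_um

    ncols = int(np.ceil(np.sqrt(spec.n_nuclei)))
    nrows = int(np.ceil(spec.n_nuclei / ncols))
    cell = int(np.ceil(2 * r_nuc + 4 * r_gran_um / px + 8))
    ny, nx = nrows * cell, ncols * cell
    nz = spec.n_planes
    z_c = (nz - 1) / 2.0

    zz = (np.arange(nz)[:, None, None] - z_c) * dz
    yy = np.arange(ny)[None, :, None] * px
    xx = np.arange(nx)[None, None, :] * px

    nucleus_labels = np.zeros((nz, ny, nx), dtype=np.int32)
    granule_mask = np.zeros((nz, ny, nx), dtype=bool)
    marker = np.full((nz, ny, nx), spec.marker_background, dtype=float)
    centers_um: list[tuple[float, float, float]] = []

    for i in range(spec.n_nuclei):
        row, col = divmod(i, ncols)
        cy = (row * cell + cell / 2 + rng.uniform(-2, 2)) * px
        cx = (col * cell + cell / 2 + rng.uniform(-2, 2)) * px
        d2 = zz**2 + (yy - cy) ** 2 + (xx - cx) ** 2
        nucleus_labels[d2 <= spec.nucleus_radius_um**2] = i + 1

        angles = rng.uniform(0, 2 * np.pi, size=spec.granules_per_nucleus)
        for theta in angles:
            gy = cy + spec.nucleus_radius_um * np.sin(theta)
            gx = cx + spec.nucleus_radius_um * np.cos(theta)
            gz_um = 0.0  # equatorial plane of the nucleus
            centers_um.append((z_c * dz, gy, gx))
            # local crop for speed
            half = r_gran_um + 4 * spec.granule_sigma_um
            z0 = max(0, int((gz_um - half) / dz + z_c))
            z1 = min(nz, int(np.ceil((gz_um + half) / dz + z_c)) + 1)
            y0 = max(0, int((gy - half) / px))
            y1 = min(ny, int(np.ceil((gy + half) / px)) + 1)
            x0 = max(0, int((gx - half) / px))
            x1 = min(nx, int(np.ceil((gx + half) / px)) + 1)
            lz = (np.arange(z0, z1)[:, None, None] - z_c) * dz - gz_um
            ly = np.arange(y0, y1)[None, :, None] * px - gy
            lx = np.arange(x0, x1)[None, None, :] * px - gx
            ld2 = lz**2 + ly**2 + lx**2
            granule_mask[z0:z1, y0:y1, x0:x1] |= ld2 <= r_gran_um**2
            marker[z0:z1, y0:y1, x0:x1] += spec.marker_granule_intensity * np.exp(
                -ld2 / (2 * spec.granule_sigma_um**2)
            )

    granule_mask &= nucleus_labels == 0  # granules are cytoplasmic

    query = np.full((nz, ny, nx), spec.cytoplasm_level, dtype=float)
    query[nucleus_labels > 0] = spec.nuclear_query_fraction * spec.cytoplasm_level
    query[granule_mask] = spec.query_enrichment_ratio * spec.cytoplasm_level

    marker_noisy = _apply_noise(marker, spec.noise_model, rng)
    query_noisy = _apply_noise(query, spec.noise_model, rng)

    stack = ImageStack(
        data=np.stack([marker_noisy, query_noisy]),
        pixel_size_um=px,
        plane_spacing_um=dz,
        channel_names=["marker", "query"],
    )
    truth = GranuleImageTruth(
        nucleus_masks=nucleus_labels,
        granule_centers=centers_um,
        granule_mask=granule_mask,
        true_ratio=spec.query_enrichment_ratio,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# condensate images
# ---------------------------------------------------------------------------

def generate_condensate_image(
    inside_mean: float,
    outside_mean: float,
    n_condensates: int = 6,
    seed: int = 0,
    condensate_radius_um: float = 2.0,
    pixel_size_um: float = 0.1,
    gaussian_sd: float = 2.0,
    marker_inside: float = 500.0,
    marker_outside: float = 20.0,
) -> tuple[ImageStack, dict]:
    """Render a two-channel 2D image of phase-separated condensates.

    The marker channel defines the dense phase (disks on a jittered
    grid); the query channel has ``inside_mean`` inside condensates and
    ``outside_mean`` in the dilute phase, plus Gaussian noise. The true
    partition ratio is ``inside_mean / outside_mean``.
    """
    if inside_mean < 0 or outside_mean < 0:
        raise InvalidSpecError("phase means must be >= 0")
    rng = np.random.default_rng(seed)
    px = pixel_size_um
    r_px = condensate_radius_um / px
    # cell wide enough to hold the condensate plus a dilute-phase border
    # that accommodates an outside ROI
    cell = int(np.ceil(2 * r_px + 2 * 2.47 / px + 10))
    ncols = int(np.ceil(np.sqrt(max(n_condensates, 1))))
    nrows = int(np.ceil(max(n_condensates, 1) / ncols))
    ny, nx = nrows * cell, ncols * cell

    yy = np.arange(ny)[:, None]
    xx = np.arange(nx)[None, :]
    mask = np.zeros((ny, nx), dtype=bool)
    centers = []
    for i in range(n_condensates):
        row, col = divmod(i, ncols)
        cy = row * cell + cell / 2 + rng.uniform(-2, 2)
        cx = col * cell + cell / 2 + rng.uniform(-2, 2)
        centers.append((cy * px, cx * px))
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2

    marker = np.where(mask, marker_inside, marker_outside).astype(float)
    query = np.where(mask, inside_mean, outside_mean).astype(float)
    noise = {"poisson_scale": 0.0, "gaussian_sd": gaussian_sd}
    marker = _apply_noise(marker, noise, rng)
    query = _apply_noise(query, noise, rng)

    stack = ImageStack(
        data=np.stack([marker[None, :, :], query[None, :, :]]),
        pixel_size_um=px,
        plane_spacing_um=1.0,
        channel_names=["marker", "query"],
    )
    truth = {
        "condensate_mask": mask,
        "centers_um": centers,
        "cell_um": cell * px,
        "radius_um": condensate_radius_um,
        "true_ratio": (inside_mean / outside_mean) if outside_mean > 0 else np.inf,
    }
    return stack, truth


def default_condensate_rois(
    truth: dict, roi_side_um: float = 2.47, n_inside: int = 6, n_outside: int = 6
) -> tuple[list[tuple[float, float, float]], list[tuple[float, float, float]]]:
    """Place square ROIs centred on condensates (inside) and in the
    dilute phase between them (outside).

    ROIs are ``(top_um, left_um, side_um)`` triples. Outside ROIs are
    put at the top-left corner region of each grid cell, clear of the
    condensate disk.
    """
    half = roi_side_um / 2
    inside = []
    for cy, cx in truth["centers_um"][:n_inside]:
        inside.append((cy - half, cx - half, roi_side_um))
    outside = []
    cell = truth["cell_um"]
    for cy, cx in truth["centers_um"][:n_outside]:
        # corner of the same grid cell: offset along the diagonal
        oy = cy - cell / 2 + 0.3
        ox = cx - cell / 2 + 0.3
        outside.append((oy, ox, roi_side_um))
    return inside, outside


# ---------------------------------------------------------------------------
# small-RNA IP/input experiments
# ---------------------------------------------------------------------------

@dataclass
class SrnaExperimentSpec:
    """Design of a synthetic Argonaute IP small-RNA experiment.

    Counts are negative-binomial around per-gene expected abundances;
    for planted targets the IP expectation is ``ip_enrichment_fold``
    times the input expectation (in RPM, with the stated library depth
    as the reads-per-million denominator). ``gene_fraction`` is the
    share of each library's mapped reads that falls on the gene table
    (the remainder emulates structural/untracked reads), which keeps
    IP library totals below the depth without rescaling planted folds.
    """

    n_genes: int = 2000
    gene_lengths: tuple[int, int] | np.ndarray = (500, 2000)
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("WT", "mutant")
    library_depth: int = 1_000_000
    nb_dispersion: float = 0.02
    true_targets: dict[str, set] | None = None
    n_default_targets: int = 500
    ip_enrichment_fold: float = 4.0
    positional_bias: dict[str, np.ndarray] | None = None
    gene_classes: np.ndarray | None = None  # per-gene profile-class labels
    geneset_labels: dict[str, str] | None = None
    abundance_sigma: float = 1.0
    gene_fraction: float = 0.5

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise InvalidSpecError("n_genes and n_replicates must be >= 1")
        if self.library_depth <= 0:
            raise InvalidSpecError("library_depth must be > 0")
        if self.ip_enrichment_fold < 1:
            raise InvalidSpecError("ip_enrichment_fold must be >= 1 for true targets")
        if self.nb_dispersion < 0:
            raise InvalidSpecError("nb_dispersion must be >= 0")
        if not 0 < self.gene_fraction <= 1:
            raise InvalidSpecError("gene_fraction must be in (0, 1]")
        if self.positional_bias is not None:
            for name, prof in self.positional_bias.items():
                prof = np.asarray(prof, dtype=float)
                if prof.ndim != 1 or prof.size < 1 or np.any(prof < 0) or prof.sum() <= 0:
                    raise InvalidSpecError(f"positional profile {name!r} invalid")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with var = mu + alpha mu^2 (Poisson if alpha=0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def generate_srna_experiment(
    spec: SrnaExperimentSpec, seed: int, with_coverage: bool = True
) -> tuple[CountExperiment, dict[str, CoverageSet], pd.DataFrame]:
    """Simulate IP/input count libraries with planted targets.

    Returns
    -------
    experiment : CountExperiment
        Gene x library counts with a design table and explicit library
        sizes (= ``spec.library_depth`` for every library).
    coverage : dict of library name -> CoverageSet
        Per-gene 1-nt coverage drawn multinomially along each gene
        following the positional profile of its class (empty dict when
        ``with_coverage`` is False).
    truth : DataFrame
        Per-gene length, abundance, profile class, geneset label and
        one ``target_<condition>`` column per condition.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    genes = np.array([f"g{i:05d}" for i in range(spec.n_genes)])
    if isinstance(spec.gene_lengths, tuple):
        lo, hi = spec.gene_lengths
        lengths = rng.integers(lo, hi + 1, size=spec.n_genes)
    else:
        lengths = np.asarray(spec.gene_lengths, dtype=int)
        if lengths.size != spec.n_genes:
            raise InvalidSpecError("gene_lengths array must have n_genes entries")

    rel = rng.lognormal(0.0, spec.abundance_sigma, size=spec.n_genes)
    rel /= rel.sum()

    if spec.true_targets is None:
        base = set(genes[rng.choice(spec.n_genes, size=min(
            spec.n_default_targets, spec.n_genes), replace=False)])
        targets = {cond: set(base) for cond in spec.conditions}
    else:
        universe = set(genes)
        targets = {}
        for cond in spec.conditions:
            tset = set(spec.true_targets.get(cond, set()))
            if not tset <= universe:
                raise InvalidSpecError("true_targets must be drawn from the gene universe")
            targets[cond] = tset

    if spec.geneset_labels is None:
        all_targets = sorted(set().union(*targets.values())) if targets else []
        labels = {}
        for g in genes:
            labels[g] = "none"
        if all_targets:
            flags = rng.random(len(all_targets)) < 0.3
            for g, f in zip(all_targets, flags):
                labels[g] = "specific" if f else "shared"
    else:
        labels = {g: spec.geneset_labels.get(g, "none") for g in genes}

    classes = (
        np.asarray(spec.gene_classes)
        if spec.gene_classes is not None
        else np.array(["uniform"] * spec.n_genes)
    )
    profiles = spec.positional_bias or {"uniform": np.ones(10)}

    design_rows = []
    count_cols = {}
    coverage: dict[str, CoverageSet] = {}
    base_mean = rel * spec.library_depth * spec.gene_fraction

    for cond in spec.conditions:
        is_target = np.isin(genes, list(targets[cond]))
        for rep in range(1, spec.n_replicates + 1):
            for role in ("input", "IP"):
                lib = f"{cond}_{role}_r{rep}"
                mean = base_mean.copy()
                if role == "IP":
                    mean = mean * np.where(is_target, spec.ip_enrichment_fold, 1.0)
                counts = _nb_draw(rng, mean, spec.nb_dispersion)
                count_cols[lib] = counts
                design_rows.append(
                    {"library": lib, "role": role, "replicate": rep, "condition": cond}
                )
                if with_coverage:
                    cov = {}
                    for gi, g in enumerate(genes):
                        total = int(counts[gi])
                        L = int(lengths[gi])
                        prof = np.asarray(profiles[classes[gi]], dtype=float)
                        # piecewise-constant profile over [0, 1) resampled
                        # to 1-nt resolution
                        idx = (np.arange(L) * prof.size) // L
                        w = prof[idx]
                        w = w / w.sum()
                        cov[g] = rng.multinomial(total, w).astype(np.int32)
                    coverage[lib] = CoverageSet(
                        per_gene=cov,
                        gene_lengths=dict(zip(genes, (int(x) for x in lengths))),
                    )

    counts_df = pd.DataFrame(count_cols, index=genes)
    design_df = pd.DataFrame(design_rows).set_index("library")
    library_sizes = pd.Series(
        float(spec.library_depth), index=counts_df.columns, name="library_size"
    )
    experiment = CountExperiment(counts_df, design_df, library_sizes)

    truth = pd.DataFrame(
        {
            "gene": genes,
            "length": lengths,
            "abundance": rel,
            "profile_class": classes,
            "geneset_label": [labels[g] for g in genes],
        }
    ).set_index("gene")
    for cond in spec.conditions:
        truth[f"target_{cond}"] = np.isin(genes, list(targets[cond]))

    return experiment, coverage, truth


# ---------------------------------------------------------------------------
# FG-dipeptide protein sequences
# ---------------------------------------------------------------------------

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Average amino-acid composition of eukaryotic proteomes (UniProt-style
#: background; rounded, renormalized at use).
DEFAULT_AA_FREQ = {
    "A": 0.0777, "C": 0.0157, "D": 0.0530, "E": 0.0656, "F": 0.0405,
    "G": 0.0691, "H": 0.0227, "I": 0.0591, "K": 0.0595, "L": 0.0960,
    "M": 0.0238, "N": 0.0427, "P": 0.0469, "Q": 0.0393, "R": 0.0526,
    "S": 0.0694, "T": 0.0550, "V": 0.0667, "W": 0.0118, "Y": 0.0311,
}


@dataclass
class FgSequenceSpec:
    """Protein sequences with planted FG-dense segments.

    ``planted_segments`` is a list of ``(start, end, fg_density)``
    triples applied to every sequence; ``fg_density`` is FG dipeptides
    per residue of segment length, at most 0.5 (one FG pair consumes
    two residues).
    """

    n_sequences: int = 10
    length: int = 400
    background_aa_freq: dict[str, float] | None = None
    planted_segments: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_sequences < 0 or self.length < 1:
            raise InvalidSpecError("n_sequences >= 0 and length >= 1 required")
        last_end = 0
        for start, end, dens in sorted(self.planted_segments):
            if not (0 <= start < end <= self.length):
                raise InvalidSpecError(
                    f"planted segment ({start}, {end}) outside sequence bounds"
                )
            if start < last_end:
                raise InvalidSpecError("planted segments must not overlap")
            if not 0 <= dens <= 0.5:
                raise InvalidSpecError("fg_density must be in [0, 0.5]")
            last_end = end


def generate_fg_sequences(
    spec: FgSequenceSpec,
) -> tuple[list[SeqRecord], list[dict]]:
    """Draw background sequences and plant FG-dense segments.

    FG pairs are placed at evenly spaced offsets inside each planted
    segment (density 0.5 therefore yields a perfect ``FGFG...`` run);
    the remaining segment positions are background draws.

    Returns FASTA-writable records and a truth list with one entry per
    (sequence, planted segment).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    freqs = dict(spec.background_aa_freq or DEFAULT_AA_FREQ)
    letters = np.array(list(AMINO_ACIDS))
    p = np.array([freqs.get(a, 0.0) for a in AMINO_ACIDS], dtype=float)
    if np.any(p < 0) or p.sum() <= 0:
        raise InvalidSpecError("background_aa_freq must be non-negative and non-null")
    p = p / p.sum()

    records, truth = [], []
    for si in range(spec.n_sequences):
        seq = rng.choice(letters, size=spec.length, p=p)
        for start, end, dens in spec.planted_segments:
            seg_len = end - start
            n_pairs = int(round(dens * seg_len))
            if n_pairs > 0:
                step = seg_len / n_pairs
                offsets = np.minimum(
                    (np.arange(n_pairs) * step).astype(int), seg_len - 2
                )
                for off in offsets:
                    seq[start + off] = "F"
                    seq[start + off + 1] = "G"
            truth.append(
                {
                    "sequence_id": f"seq{si:04d}",
                    "start": start,
                    "end": end,
                    "fg_density": dens,
                    "n_pairs": n_pairs,
                }
            )
        records.append(
            SeqRecord(Seq("".join(seq)), id=f"seq{si:04d}", description="")
        )
    return records, truth
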