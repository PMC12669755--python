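"""Argonaute IP small-RNA target calling and metagene profiling.

A gene is called an Argonaute target when, in **every** biological
replicate, its IP library abundance reaches a minimum RPM (reads per
million mapped) and the IP/input fold change reaches a minimum — the
replicate-consistent rule with defaults of 5 RPM and 2-fold across
three replicates. Target sets from two conditions are compared with
exact set algebra (shared / exclusive, Venn-style), and positional
targeting signatures are summarized as metagene profiles: each target
gene rescaled to 100 length bins, mean coverage (RPM) per bin averaged
over targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountExperiment",
    "CoverageSet",
    "TargetCallingParams",
    "TargetSetComparison",
    "MetageneProfile",
    "rpm_normalize",
    "call_targets",
    "compare_target_sets",
    "classify_differential_targets",
    "metagene_profile",
    "profile_similarity",
]


class DesignError(ValueError):
    """The library design table violates the IP/input pairing contract."""


@dataclass
class CountExperiment:
    """Gene x library counts with an IP/input replicate design.

    Parameters
    ----------
    counts : DataFrame, genes x libraries
        Non-negative integer counts.
    design : DataFrame indexed by library
        Columns ``role`` ("IP" or "input"), ``replicate`` (int),
        ``condition`` (label). Every (condition, replicate) must have
        exactly one IP and one input library.
    library_sizes : Series, optional
        Total mapped reads per library; defaults to column sums.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise DesignError(f"libraries missing from design: {sorted(missing)}")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        for col in ("role", "replicate", "condition"):
            if col not in self.design.columns:
                raise DesignError(f"design lacks required column {col!r}")
        bad_roles = set(self.design["role"]) - {"IP", "input"}
        if bad_roles:
            raise DesignError(f"unknown roles in design: {sorted(bad_roles)}")
        for (cond, rep), grp in self.design.groupby(["condition", "replicate"]):
            roles = sorted(grp["role"])
            if roles != ["IP", "input"]:
                raise DesignError(
                    f"(condition={cond!r}, replicate={rep}) must have exactly one "
                    f"IP and one input library; found roles {roles}"
                )
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
            self.library_sizes.name = "library_size"
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)
            if self.library_sizes.isna().any():
                raise DesignError("library_sizes missing for some libraries")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.design["condition"].unique())

    def libraries(self, condition: str, role: str) -> pd.DataFrame:
        sub = self.design[
            (self.design["condition"] == condition) & (self.design["role"] == role)
        ]
        return sub.sort_values("replicate")


@dataclass
class CoverageSet:
    """Per-gene 1-nt coverage (0-based positions along each gene)."""

    per_gene: dict[str, np.ndarray]
    gene_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for g, arr in self.per_gene.items():
            if len(arr) != self.gene_lengths.get(g):
                raise ValueError(f"coverage length mismatch for gene {g!r}")


@dataclass
class TargetCallingParams:
    """The replicate-consistent target rule's thresholds.

    Defaults follow the published rule: at least 5 RPM in the IP and an
    IP/input fold change of at least 2, required in every replicate.
    ``pseudocount_rpm`` guards the fold change against zero-input genes;
    0 reproduces strict division (infinite fold change when input is 0
    and IP is positive).
    """

    min_rpm: float = 5.0
    min_fold_change: float = 2.0
    require_all_replicates: bool = True
    pseudocount_rpm: float = 0.1

    def validate(self) -> None:
        if self.min_rpm < 0:
            raise ValueError("min_rpm must be >= 0")
        if self.min_fold_change < 1:
            raise ValueError("min_fold_change must be >= 1")
        if self.pseudocount_rpm < 0:
            raise ValueError("pseudocount_rpm must be >= 0")


@dataclass
class TargetSetComparison:
    """Shared/exclusive targets between two conditions (Venn algebra)."""

    shared: set
    a_only: set
    b_only: set

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
            "a_total": len(self.shared) + len(self.a_only),
            "b_total": len(self.shared) + len(self.b_only),
        }

    @property
    def percent_exclusive(self) -> dict[str, int]:
        """Exclusive set size as integer percent of its parent set."""
        s = self.sizes
        out = {}
        out["a_only_pct"] = (
            int(round(100 * s["a_only"] / s["a_total"])) if s["a_total"] else 0
        )
        out["b_only_pct"] = (
            int(round(100 * s["b_only"] / s["b_total"])) if s["b_total"] else 0
        )
        return out


@dataclass
class MetageneProfile:
    """Mean coverage (RPM) over 100 relative-length bins."""

    bins: np.ndarray
    n_targets: int
    track_role: str = ""
    per_gene: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)


def rpm_normalize(experiment: CountExperiment) -> pd.DataFrame:
    """Reads-per-million normalization: counts / library size x 1e6."""
    sizes = experiment.library_sizes
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive for RPM normalization")
    return experiment.counts.div(sizes, axis=1) * 1e6


def call_targets(
    experiment: CountExperiment,
    condition: str,
    params: TargetCallingParams | None = None,
) -> tuple[set, pd.DataFrame]:
    """Call Argonaute targets with the replicate-consistent rule.

    A gene is a target iff, for every replicate ``r`` of ``condition``:
    ``IP_rpm >= min_rpm`` and
    ``(IP_rpm + pc) / (input_rpm + pc) >= min_fold_change``.
    With ``require_all_replicates=False`` a single passing replicate
    suffices.

    Returns the target gene set and a per-gene evidence table with
    per-replicate RPM and fold-change columns and an ``is_target`` flag.
    """
    params = params or TargetCallingParams()
    params.validate()
    if condition not in set(experiment.design["condition"]):
        raise DesignError(f"condition {condition!r} not present in design")
    rpm = rpm_normalize(experiment)
    ip_libs = experiment.libraries(condition, "IP")
    input_libs = experiment.libraries(condition, "input")

    pc = params.pseudocount_rpm
    evidence = pd.DataFrame(index=experiment.counts.index)
    per_rep_pass = []
    if len(ip_libs) != len(input_libs) or len(ip_libs) == 0:
        raise DesignError(f"condition {condition!r} lacks complete IP/input pairs")
    for (ip_lib, ip_row), (in_lib, in_row) in zip(
        ip_libs.iterrows(), input_libs.iterrows()
    ):
        rep_id = ip_row["replicate"]
        if in_row["replicate"] != rep_id:
            raise DesignError("IP/input replicate indices do not align")
        ip_rpm = rpm[ip_lib]
        in_rpm = rpm[in_lib]
        evidence[f"ip_rpm_r{rep_id}"] = ip_rpm
        evidence[f"input_rpm_r{rep_id}"] = in_rpm
        with np.errstate(divide="ignore", invalid="ignore"):
            if pc > 0:
                fc = (ip_rpm + pc) / (in_rpm + pc)
            else:
                fc = np.where(
                    in_rpm > 0,
                    ip_rpm / np.where(in_rpm > 0, in_rpm, 1.0),
                    np.where(ip_rpm > 0, np.inf, np.nan),
                )
                fc = pd.Series(fc, index=ip_rpm.index)
        evidence[f"fc_r{rep_id}"] = fc
        passes = (ip_rpm >= params.min_rpm) & (fc >= params.min_fold_change)
        per_rep_pass.append(passes.fillna(False))

    pass_mat = pd.concat(per_rep_pass, axis=1)
    if params.require_all_replicates:
        is_target = pass_mat.all(axis=1)
    else:
        is_target = pass_mat.any(axis=1)
    evidence["n_replicates_pass"] = pass_mat.sum(axis=1)
    evidence["is_target"] = is_target
    return set(evidence.index[is_target]), evidence


def compare_target_sets(set_a: set, set_b: set) -> TargetSetComparison:
    """Exact Venn algebra between two target sets."""
    set_a, set_b = set(set_a), set(set_b)
    return TargetSetComparison(
        shared=set_a & set_b, a_only=set_a - set_b, b_only=set_b - set_a
    )


def classify_differential_targets(
    experiment: CountExperiment,
    condition_a: str,
    condition_b: str,
    method: str = "simple",
    threshold: float = 1.0,
    external_table: pd.DataFrame | None = None,
    padj_max: float = 0.05,
    pseudocount_rpm: float = 0.1,
) -> dict[str, set]:
    """Flag genes whose IP signal changed between two conditions.

    method "simple"
        Per-replicate IP log2 fold change (condition_b over
        condition_a, pseudocounted RPM); a gene is flagged when
        ``|median log2FC| >= threshold`` and the sign is consistent
        across replicates. ``decreased`` means lower in condition_b.
    method "external"
        Consume a per-gene table (columns ``log2fc``, ``padj``) from an
        external differential-expression engine (e.g. a count-model
        fit); apply ``padj < padj_max`` and ``|log2fc| >= threshold``.
        Genes absent from the table are treated as unchanged.
    """
    for cond in (condition_a, condition_b):
        if cond not in set(experiment.design["condition"]):
            raise DesignError(f"condition {cond!r} not present in design")

    if method == "external":
        if external_table is None:
            raise ValueError("method 'external' requires external_table")
        tab = external_table.reindex(experiment.counts.index)
        missing = tab["log2fc"].isna()
        sig = (~missing) & (tab["padj"] < padj_max) & (tab["log2fc"].abs() >= threshold)
        decreased = set(tab.index[sig & (tab["log2fc"] < 0)])
        increased = set(tab.index[sig & (tab["log2fc"] > 0)])
        return {"decreased": decreased, "increased": increased,
                "missing": set(tab.index[missing])}
    if method != "simple":
        raise ValueError(f"unknown method {method!r}")

    rpm = rpm_normalize(experiment)
    ip_a = experiment.libraries(condition_a, "IP")
    ip_b = experiment.libraries(condition_b, "IP")
    if len(ip_a) != len(ip_b):
        raise DesignError("conditions have unequal replicate counts")
    pc = pseudocount_rpm
    l2fc = []
    for (lib_a, _), (lib_b, _) in zip(ip_a.iterrows(), ip_b.iterrows()):
        l2fc.append(np.log2((rpm[lib_b] + pc) / (rpm[lib_a] + pc)))
    l2fc = pd.concat(l2fc, axis=1)
    med = l2fc.median(axis=1)
    consistent = (np.sign(l2fc) == np.sign(med).values[:, None]).all(axis=1)
    flagged = (med.abs() >= threshold) & consistent & (med != 0)
    return {
        "decreased": set(med.index[flagged & (med < 0)]),
        "increased": set(med.index[flagged & (med > 0)]),
    }


def metagene_profile(
    coverage: CoverageSet,
    targets: set,
    library_size: float,
    n_bins: int = 100,
    track_role: str = "",
) -> MetageneProfile:
    """Size-normalized mean-coverage profile over a target set.

    Each gene's positions map to bins by ``floor(p * n_bins / length)``
    (0-based, half-open). The per-gene bin value is the mean RPM over
    positions mapped to that bin (0 where a short gene leaves a bin
    empty); the profile is the unweighted mean over target genes.
    """
    targets = sorted(set(targets))
    if not targets:
        raise ValueError("empty target set")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    per_gene_rows = np.zeros((len(targets), n_bins), dtype=float)
    for i, g in enumerate(targets):
        if g not in coverage.per_gene:
            raise KeyError(f"no coverage for target gene {g!r}")
        counts = np.asarray(coverage.per_gene[g], dtype=float)
        L = counts.size
        rpm = counts * 1e6 / library_size
        bins = (np.arange(L) * n_bins) // L
        sums = np.bincount(bins, weights=rpm, minlength=n_bins)
        npos = np.bincount(bins, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            row = np.where(npos > 0, sums / np.maximum(npos, 1), 0.0)
        per_gene_rows[i] = row
    profile = per_gene_rows.mean(axis=0)
    per_gene = pd.DataFrame(per_gene_rows, index=targets)
    return MetageneProfile(
        bins=profile, n_targets=len(targets), track_role=track_role, per_gene=per_gene
    )


def profile_similarity(p: MetageneProfile, q: MetageneProfile) -> float:
    """Pearson correlation between two metagene profiles."""
    a, b = np.asarray(p.bins, float), np.asarray(q.bins, float)
    if a.size != b.size:
        raise ValueError("profiles must have equal bin counts")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("profile correlation undefined for zero-variance profile")
    return float(np.corrcoef(a, b)[0, 1])
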