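"""The two-condition nucleosome-dynamics model and its fitted results.

`NucleosomeDynamics` is built from two MNase-seq read sets (reference and
perturbed) plus a gene annotation — from files, from in-memory objects, or
from a synthetic configuration with planted ground truth.  ``fit()`` runs
the full chain (clonal filtering, read adjustment, occupancy, quantile
normalization, nucleosome calling, Poisson differential test and dynamic
classification, NDR lengths and deltas at TSS/TTS, meta-gene profiles and
−1 nucleosome localization, promoter enrichment) and returns a
`NucleosomeDynamicsResults` carrying every intermediate and headline
estimate, with a ``summary()`` table and, when ground truth is available,
planted-perturbation recovery diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dynamics as dyn
from . import enrichment as enr
from . import metagene as mg
from . import ndr as ndrmod
from . import occupancy as occ
from .io import GenomeAnnotation, OccupancyTrack, ReadSet
from .simulate import SyntheticConfig, SyntheticTruth, build_truth, sample_reads

__all__ = ["NucleosomeDynamics", "NucleosomeDynamicsResults"]


class NucleosomeDynamics:
    """Model of condition-dependent nucleosome dynamics between two samples.

    Parameters
    ----------
    reads_ref, reads_alt
        Mapped reads of the reference (e.g. wild type) and perturbed
        condition.
    annotation
        Gene annotation with strand-resolved TSS/TTS and chromosome sizes.
    occupancy_config, dynamics_config, ndr_config, promoter_window
        Stage parameters; defaults follow the analysis this package
        implements (clonal Poisson cutoff 1e-10, 73 bp occupancy footprint,
        FDR < 0.005, 65 bp NDR anchor rule, promoter window −350..+50).
    truth
        Optional planted ground truth (set automatically by
        ``from_synthetic``); enables recovery diagnostics.
    """

    def __init__(self, reads_ref: ReadSet, reads_alt: ReadSet,
                 annotation: GenomeAnnotation,
                 occupancy_config: occ.OccupancyConfig | None = None,
                 dynamics_config: dyn.DynamicsConfig | None = None,
                 ndr_config: ndrmod.NDRConfig | None = None,
                 promoter_window: enr.PromoterWindow | None = None,
                 metagene_window: int = 1000,
                 metagene_bin: int = 50,
                 labels: tuple[str, str] = ("wt", "mut"),
                 decile_fraction: float = 0.10,
                 truth: SyntheticTruth | None = None):
        self.reads = {labels[0]: reads_ref, labels[1]: reads_alt}
        self.annotation = annotation
        self.occupancy_config = occupancy_config or occ.OccupancyConfig()
        self.dynamics_config = dynamics_config or dyn.DynamicsConfig()
        self.ndr_config = ndr_config or ndrmod.NDRConfig()
        self.promoter_window = promoter_window or enr.PromoterWindow()
        self.metagene_window = int(metagene_window)
        self.metagene_bin = int(metagene_bin)
        self.labels = labels
        self.decile_fraction = float(decile_fraction)
        self.truth = truth
        problems = (self.occupancy_config.validate()
                    + self.dynamics_config.validate()
                    + self.ndr_config.validate()
                    + self.promoter_window.validate())
        if problems:
            raise ValueError("invalid model configuration: " + "; ".join(problems))

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_synthetic(cls, config: SyntheticConfig | None = None,
                       truth: SyntheticTruth | None = None,
                       **kwargs) -> "NucleosomeDynamics":
        """Build the model from a synthetic configuration (or prebuilt truth)."""
        if truth is None:
            truth = build_truth(config or SyntheticConfig())
        reads = {c: sample_reads(truth, c) for c in truth.conditions}
        ref, alt = truth.conditions[0], truth.conditions[1]
        return cls(reads[ref], reads[alt], truth.annotation,
                   labels=(ref, alt), truth=truth, **kwargs)

    @classmethod
    def from_files(cls, reads_ref_path, reads_alt_path, annotation_path,
                   chrom_sizes_path=None, paired: bool = False,
                   **kwargs) -> "NucleosomeDynamics":
        from . import io as nio

        sizes = nio.read_chrom_sizes(chrom_sizes_path) if chrom_sizes_path else None
        annotation = nio.read_gff3(annotation_path, chrom_sizes=sizes)
        sizes = annotation.chrom_sizes

        def _load(path):
            path = str(path)
            if path.endswith(".sam"):
                rs, _report = nio.read_sam_reads(path, chrom_sizes=sizes)
                return rs
            return nio.read_bed_reads(path, chrom_sizes=sizes, paired=paired)

        return cls(_load(reads_ref_path), _load(reads_alt_path), annotation,
                   **kwargs)

    # -- fitting -------------------------------------------------------------

    def fit(self) -> "NucleosomeDynamicsResults":
        sizes = self.annotation.chrom_sizes
        ref, alt = self.labels
        cfg = self.occupancy_config

        filtered, clonal_reports, fragment_sizes, adjusted = {}, {}, {}, {}
        raw_tracks = {}
        for label in self.labels:
            reads = self.reads[label]
            reads, report = occ.remove_clonal_reads(
                reads, sizes, cutoff=cfg.clonal_pvalue_cutoff)
            filtered[label] = reads
            clonal_reports[label] = report
            if cfg.fragment_size_override is not None:
                fragment_sizes[label] = int(cfg.fragment_size_override)
            else:
                fragment_sizes[label] = occ.estimate_fragment_size(reads, sizes)
            adjusted[label] = occ.adjust_reads(reads, fragment_sizes[label], sizes)
            raw_tracks[label] = occ.compute_coverage(
                adjusted[label], sizes, half_width=cfg.footprint_half_width,
                sample=label)

        if cfg.normalization == "quantile":
            norm = occ.quantile_normalize([raw_tracks[ref], raw_tracks[alt]])
            tracks = {ref: norm[0], alt: norm[1]}
        else:
            tracks = raw_tracks

        calls = {
            label: dyn.call_nucleosomes(
                tracks[label], adjusted[label],
                spacing=self.dynamics_config.summit_spacing,
                half_width=cfg.footprint_half_width)
            for label in self.labels
        }
        pvals = dyn.differential_signal(
            tracks[ref], tracks[alt], pseudocount=self.dynamics_config.pseudocount)
        dynamics = dyn.match_and_classify(
            calls[ref], calls[alt], pvals, self.dynamics_config,
            adjusted_wt=adjusted[ref], adjusted_mut=adjusted[alt],
            track_wt=tracks[ref], track_mut=tracks[alt])
        fraction = dyn.dynamic_fraction(dynamics, calls[ref])

        thresholds = {label: ndrmod.genome_threshold(tracks[label])
                      for label in self.labels}
        ndr_calls = {
            (label, anchor): ndrmod.ndr_table(
                tracks[label], self.annotation, anchor=anchor,
                threshold=thresholds[label], config=self.ndr_config)
            for label in self.labels for anchor in ("tss", "tts")
        }
        delta = {anchor: ndrmod.delta_ndr(ndr_calls[(ref, anchor)],
                                          ndr_calls[(alt, anchor)])
                 for anchor in ("tss", "tts")}
        shrink_set, expand_set = ndrmod.select_deciles(
            delta["tss"], fraction=self.decile_fraction)

        profiles = {
            (label, anchor): mg.align_profiles(
                tracks[label], self.annotation, anchor=anchor,
                window=self.metagene_window)
            for label in self.labels for anchor in ("tss", "tts")
        }
        profiles_shrink = {
            label: mg.align_profiles(tracks[label], self.annotation,
                                     anchor="tss", window=self.metagene_window,
                                     gene_ids=shrink_set)
            for label in self.labels
        }
        minus_one = {}
        try:
            minus_one["all"] = {
                label: mg.minus_one_position(profiles[(label, "tss")])
                for label in self.labels}
            minus_one["all"]["shift"] = (minus_one["all"][ref]
                                         - minus_one["all"][alt])
        except mg.MetageneError:
            minus_one["all"] = None
        try:
            minus_one["shrink_decile"] = {
                label: mg.minus_one_position(profiles_shrink[label])
                for label in self.labels}
            minus_one["shrink_decile"]["shift"] = (
                minus_one["shrink_decile"][ref]
                - minus_one["shrink_decile"][alt])
        except mg.MetageneError:
            minus_one["shrink_decile"] = None

        fraction_profile, genome_avg = mg.dynamic_fraction_profile(
            dynamics, calls[ref], self.annotation, anchor="tss",
            bin_size=self.metagene_bin, window=self.metagene_window)

        try:
            promoter = enr.promoter_enrichment(
                dynamics, calls[ref], self.annotation, self.promoter_window)
        except enr.EnrichmentError:
            promoter = None

        results = NucleosomeDynamicsResults(
            model=self,
            clonal_reports=clonal_reports,
            fragment_sizes=fragment_sizes,
            tracks=tracks,
            calls=calls,
            pvalue_tracks=pvals,
            dynamics=dynamics,
            dynamic_fraction=fraction,
            ndr_thresholds=thresholds,
            ndr_calls=ndr_calls,
            delta_ndr=delta,
            shrink_set=shrink_set,
            expand_set=expand_set,
            profiles=profiles,
            profiles_shrink=profiles_shrink,
            minus_one=minus_one,
            dynamic_fraction_profile=fraction_profile,
            genome_dynamic_percent=genome_avg,
            promoter_enrichment=promoter,
        )
        if self.truth is not None:
            results.recovery = results._score_recovery(self.truth)
        return results


@dataclass
class NucleosomeDynamicsResults:
    """Fitted estimates, diagnostics and tables of a NucleosomeDynamics model."""

    model: NucleosomeDynamics
    clonal_reports: dict
    fragment_sizes: dict
    tracks: dict[str, OccupancyTrack]
    calls: dict[str, pd.DataFrame]
    pvalue_tracks: dict[str, np.ndarray]
    dynamics: pd.DataFrame
    dynamic_fraction: float
    ndr_thresholds: dict[str, float]
    ndr_calls: dict
    delta_ndr: dict[str, pd.DataFrame]
    shrink_set: list[str]
    expand_set: list[str]
    profiles: dict
    profiles_shrink: dict
    minus_one: dict
    dynamic_fraction_profile: pd.DataFrame
    genome_dynamic_percent: float
    promoter_enrichment: enr.EnrichmentResult | None
    recovery: dict | None = None

    # -- recovery against planted truth -------------------------------------

    def _score_recovery(self, truth: SyntheticTruth,
                        match_tolerance: int = 74) -> dict:
        """Score the fitted dynamics/NDR calls against the planted truth."""
        ref, alt = self.model.labels
        spec = truth.config.perturbation
        out: dict = {}

        wt_dyads = truth.dyads[ref]
        mut_dyads = truth.dyads[alt]
        retained = self.dynamics
        if "dynamic" in retained.columns:
            retained = retained[retained["dynamic"]]

        def _nearest_record(chrom, pos):
            sub = retained[retained["chrom"] == chrom]
            anchor_col = sub["summit_wt"].where(sub["summit_wt"] >= 0,
                                                sub["summit_mut"])
            if len(sub) == 0:
                return None
            d = (anchor_col - pos).abs()
            k = d.idxmin()
            return sub.loc[k] if d.loc[k] <= match_tolerance else None

        # occupancy class: planted -1 nucleosomes with a fold change
        occ_genes = truth.genes_with_label("occupancy")
        hits = 0
        for gid in occ_genes:
            site = wt_dyads[(wt_dyads["gene_id"] == gid)
                            & (wt_dyads["role"] == "-1")].iloc[0]
            rec = _nearest_record(site["chrom"], site["pos"])
            if rec is not None and rec["category"] == "occupancy_change":
                hits += 1
        out["occupancy_sensitivity"] = hits / len(occ_genes) if occ_genes else np.nan
        out["n_occupancy_planted"] = len(occ_genes)

        # shift class: every planted dyad moved by shift_bp
        shift_rows = wt_dyads.join(
            mut_dyads["pos"].rename("pos_mut"))
        shift_rows = shift_rows[
            shift_rows["gene_id"].isin(truth.genes_with_label("shift"))]
        planted_delta = (shift_rows["pos_mut"] - shift_rows["pos"]).abs()
        shift_rows = shift_rows[planted_delta > 0]
        recovered, within = 0, 0
        for _i, site in shift_rows.iterrows():
            rec = _nearest_record(site["chrom"], site["pos"])
            if rec is None or rec["summit_wt"] < 0 or rec["summit_mut"] < 0:
                continue
            recovered += 1
            if abs(abs(rec["delta_summit"]) - spec.shift_bp) <= 10:
                within += 1
        out["n_shift_sites_planted"] = int(len(shift_rows))
        out["n_shift_sites_recovered"] = recovered
        out["shift_within_10bp_of_planted"] = (within / recovered
                                               if recovered else np.nan)

        # ndr_shrink class: per-gene delta NDR at TSS
        shrink_genes = truth.genes_with_label("ndr_shrink")
        delta = self.delta_ndr["tss"]
        out["median_delta_ndr_shrink"] = (
            float(delta.loc[shrink_genes, "delta"].median())
            if shrink_genes else np.nan)
        unperturbed = truth.genes_with_label("none")
        out["median_delta_ndr_unperturbed"] = (
            float(delta.loc[unperturbed, "delta"].median())
            if unperturbed else np.nan)
        if shrink_genes:
            found = set(self.shrink_set)
            planted = set(shrink_genes)
            out["shrink_decile_jaccard"] = (
                len(found & planted) / len(found | planted))
        else:
            out["shrink_decile_jaccard"] = np.nan

        # -1 nucleosome shift over the planted shrink genes, measured per
        # gene from the called nucleosomes (robust to NDR-width smearing of
        # the averaged profile), plus the profile-peak variant for reference
        if shrink_genes:
            d_ref = mg.per_gene_minus_one(self.calls[ref],
                                          self.model.annotation,
                                          gene_ids=shrink_genes)
            d_alt = mg.per_gene_minus_one(self.calls[alt],
                                          self.model.annotation,
                                          gene_ids=shrink_genes)
            shift = (d_ref - d_alt).dropna()
            # median: a gene whose -1 is called in one condition only pairs
            # the -1 with the -2 and lands a whole nucleosome off
            out["minus_one_shift_shrink_planted"] = (
                float(shift.median()) if len(shift) else np.nan)
            out["n_shrink_genes_with_minus_one"] = int(len(shift))
            try:
                profs = {
                    label: mg.align_profiles(
                        self.tracks[label], self.model.annotation,
                        anchor="tss", window=self.model.metagene_window,
                        gene_ids=shrink_genes)
                    for label in self.model.labels}
                out["minus_one_shift_shrink_planted_profile"] = \
                    mg.minus_one_shift(profs[ref], profs[alt])
            except mg.MetageneError:
                out["minus_one_shift_shrink_planted_profile"] = np.nan
        return out

    # -- reporting -----------------------------------------------------------

    def headline(self) -> dict:
        """Machine-readable headline numbers of the fit."""
        ref, alt = self.model.labels
        head = {
            "n_reads": {label: int(r["n_input"])
                        for label, r in self.clonal_reports.items()},
            "n_clonal_removed": {label: int(r["n_removed"])
                                 for label, r in self.clonal_reports.items()},
            "fragment_sizes": {k: int(v) for k, v in self.fragment_sizes.items()},
            "n_calls": {label: int(len(c)) for label, c in self.calls.items()},
            "n_dynamic": int(len(self.dynamics)),
            "dynamic_fraction": float(self.dynamic_fraction),
            "genome_dynamic_percent": float(self.genome_dynamic_percent),
            "ndr_thresholds": {k: float(v) for k, v in self.ndr_thresholds.items()},
            "median_delta_ndr_tss": float(self.delta_ndr["tss"]["delta"].median()),
            "median_delta_ndr_tts": float(self.delta_ndr["tts"]["delta"].median()),
            "n_shrink_decile": len(self.shrink_set),
            "n_expand_decile": len(self.expand_set),
        }
        if self.minus_one.get("all"):
            head["minus_one_distance"] = {
                ref: float(self.minus_one["all"][ref]),
                alt: float(self.minus_one["all"][alt]),
            }
            head["minus_one_shift"] = float(self.minus_one["all"]["shift"])
        if self.minus_one.get("shrink_decile"):
            head["minus_one_shift_shrink_decile"] = float(
                self.minus_one["shrink_decile"]["shift"])
        if self.promoter_enrichment is not None:
            head["promoter_odds_ratio"] = float(self.promoter_enrichment.odds_ratio)
            head["promoter_p_value"] = float(self.promoter_enrichment.p_value)
        if self.recovery is not None:
            head["recovery"] = {
                k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in self.recovery.items()}
        return head

    def summary(self) -> str:
        """Human-readable summary table of the fit."""
        ref, alt = self.model.labels
        h = self.headline()
        lines = []
        rule = "=" * 64
        lines.append(rule)
        lines.append("Nucleosome dynamics between conditions "
                     f"'{ref}' (reference) and '{alt}'")
        lines.append(rule)
        for label in self.model.labels:
            lines.append(
                f"{label:>8}: {h['n_reads'][label]:>9d} reads "
                f"({h['n_clonal_removed'][label]} clonal removed), "
                f"fragment size {h['fragment_sizes'][label]} bp, "
                f"{h['n_calls'][label]} nucleosomes called")
        lines.append("-" * 64)
        lines.append(f"dynamic nucleosomes (FDR < "
                     f"{self.model.dynamics_config.fdr_cutoff:g}): "
                     f"{h['n_dynamic']} "
                     f"({100 * h['dynamic_fraction']:.2f}% of {ref} calls)")
        if self.dynamics is not None and len(self.dynamics):
            counts = self.dynamics["category"].value_counts()
            for cat, n in counts.items():
                lines.append(f"{'':>8}  {cat}: {n}")
        if "promoter_odds_ratio" in h:
            lines.append(
                f"promoter enrichment (TSS "
                f"-{self.model.promoter_window.upstream}..+"
                f"{self.model.promoter_window.downstream}): "
                f"OR = {h['promoter_odds_ratio']:.2f}, "
                f"p = {h['promoter_p_value']:.3g}")
        if "minus_one_distance" in h:
            lines.append(
                f"average -1 nucleosome: {h['minus_one_distance'][ref]:.0f} bp "
                f"({ref}) vs {h['minus_one_distance'][alt]:.0f} bp ({alt}) "
                f"upstream of TSS "
                f"(shift toward TSS: {h['minus_one_shift']:.0f} bp)")
        if "minus_one_shift_shrink_decile" in h:
            lines.append(
                f"  -1 shift over the top-shrink decile: "
                f"{h['minus_one_shift_shrink_decile']:.0f} bp")
        lines.append(
            f"NDR delta ({ref} - {alt}): median TSS "
            f"{h['median_delta_ndr_tss']:.0f} bp, median TTS "
            f"{h['median_delta_ndr_tts']:.0f} bp; deciles "
            f"{h['n_shrink_decile']} shrink / {h['n_expand_decile']} expand genes")
        if self.recovery is not None:
            lines.append("-" * 64)
            lines.append("recovery of planted perturbations:")
            r = self.recovery
            if np.isfinite(r.get("occupancy_sensitivity", np.nan)):
                lines.append(
                    f"  occupancy-change sensitivity: "
                    f"{100 * r['occupancy_sensitivity']:.0f}% "
                    f"of {r['n_occupancy_planted']} planted promoters")
            if np.isfinite(r.get("shift_within_10bp_of_planted", np.nan)):
                lines.append(
                    f"  shift recovery: {r['n_shift_sites_recovered']} of "
                    f"{r['n_shift_sites_planted']} planted sites matched; "
                    f"{100 * r['shift_within_10bp_of_planted']:.0f}% of those "
                    f"within 10 bp of the planted shift")
            if np.isfinite(r.get("median_delta_ndr_shrink", np.nan)):
                lines.append(
                    f"  median delta-NDR at planted shrink genes: "
                    f"{r['median_delta_ndr_shrink']:.0f} bp "
                    f"(unperturbed: {r['median_delta_ndr_unperturbed']:.0f} bp)")
            if np.isfinite(r.get("shrink_decile_jaccard", np.nan)):
                lines.append(
                    f"  Jaccard(top-shrink decile, planted shrink set): "
                    f"{r['shrink_decile_jaccard']:.2f}")
            if np.isfinite(r.get("minus_one_shift_shrink_planted", np.nan)):
                lines.append(
                    f"  -1 shift at planted shrink genes (per-gene): "
                    f"{r['minus_one_shift_shrink_planted']:.0f} bp")
        lines.append(rule)
        return "\n".join(lines)
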