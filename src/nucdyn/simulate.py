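"""Two-condition synthetic MNase-seq generator with planted, labelled perturbations.

The generator lays out a small multi-chromosome genome as an array of gene
units.  Each unit carries, in gene orientation: two upstream nucleosomes
(−2, −1), a promoter nucleosome-depleted region (NDR) of variable width
ending at the TSS, a +1 nucleosome and a phased gene-body array, a
terminator NDR starting at the TTS, and one downstream nucleosome.  Reads
for each condition are drawn from the planted nucleosome landscape:
nucleosome choice proportional to its expected occupancy weight, dyad
jitter from that nucleosome's fuzziness, fragment length from a truncated
normal, plus a small uniform background.

Perturbation classes (applied in the "mut" condition at disjoint gene sets):

``occupancy``
    the −1 nucleosome's expected occupancy is multiplied by
    ``occupancy_fold`` (default 2).
``shift``
    the promoter-proximal nucleosomes (−2, −1, +1) slide coherently by
    ``shift_bp`` so that the −1 nucleosome approaches the TSS; the NDR
    length is unchanged (the depletion slides with the trio), keeping the
    perturbation promoter-local.
``fuzziness``
    the −1 nucleosome's dyad jitter SD is multiplied by
    ``fuzziness_factor`` (default 2).
``ndr_shrink``
    only the upstream (−2, −1) nucleosomes slide toward the TSS by
    ``ndr_shrink_bp`` (default 44, the order of the promoter effect this
    pipeline is meant to detect), shrinking the promoter NDR.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .io import (
    GenomeAnnotation,
    ReadSet,
    ReadRecord,
    READ_COLUMNS,
    write_bed_reads,
    write_gff3,
    write_chrom_sizes,
    sha256_file,
)

__all__ = [
    "PerturbationSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "SizingError",
    "build_truth",
    "sample_reads",
    "write_fixture",
]

PERTURBATION_CLASSES = ("occupancy", "shift", "fuzziness", "ndr_shrink")


class SizingError(ValueError):
    """The requested genes do not fit into the requested genome."""


@dataclass(frozen=True)
class PerturbationSpec:
    """Per-class perturbation magnitudes applied in the mutant condition."""

    occupancy_fold: float = 2.0
    shift_bp: int = 40
    fuzziness_factor: float = 2.0
    ndr_shrink_bp: int = 44

    def validate(self) -> list[str]:
        errors = []
        if self.occupancy_fold <= 0:
            errors.append("perturbation.occupancy_fold must be > 0")
        if self.shift_bp <= 0:
            errors.append("perturbation.shift_bp must be > 0")
        if self.fuzziness_factor <= 0:
            errors.append("perturbation.fuzziness_factor must be > 0")
        if self.ndr_shrink_bp <= 0:
            errors.append("perturbation.ndr_shrink_bp must be > 0")
        return errors


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted genome and the sequencing model.

    ``perturbed_fraction`` is the fraction of genes planted *per
    perturbation class*; the classes are drawn disjointly, so the total
    perturbed fraction is ``perturbed_fraction * len(classes)``.
    ``depth`` is the total number of fragments sampled per condition.
    """

    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes: int = 250
    nucleosome_len: int = 147
    linker_len: int = 18
    ndr_width_mean: float = 140.0
    ndr_width_sd: float = 25.0
    tts_ndr_width_mean: float = 100.0
    tts_ndr_width_sd: float = 20.0
    min_ndr_width: int = 60
    occupancy_mean: float = 1.0
    occupancy_dispersion: float = 0.3  # coefficient of variation of weights
    fuzziness_sd: float = 20.0
    fragment_len_mean: float = 150.0
    fragment_len_sd: float = 15.0
    fragment_len_bounds: tuple[int, int] = (100, 250)
    read_len: int = 50
    depth: int = 100_000
    background_fraction: float = 0.02
    perturbed_fraction: float = 0.10
    classes: tuple[str, ...] = PERTURBATION_CLASSES
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    paired_end: bool = False
    seed: int = 0

    def validate(self) -> list[str]:
        errors = []
        positive = [
            "n_chromosomes", "chrom_length", "n_genes", "nucleosome_len",
            "linker_len", "ndr_width_mean", "tts_ndr_width_mean",
            "min_ndr_width", "occupancy_mean", "fragment_len_mean", "read_len",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be strictly positive")
        for name in ["ndr_width_sd", "tts_ndr_width_sd", "occupancy_dispersion",
                     "fuzziness_sd", "fragment_len_sd"]:
            if getattr(self, name) < 0:
                errors.append(f"{name} must be non-negative")
        if not 0.0 <= self.perturbed_fraction <= 1.0:
            errors.append("perturbed_fraction must be in [0, 1]")
        if not 0.0 <= self.background_fraction < 1.0:
            errors.append("background_fraction must be in [0, 1)")
        if self.depth < 0:
            errors.append("depth must be >= 0")
        lo, hi = self.fragment_len_bounds
        if not 0 < lo < hi:
            errors.append("fragment_len_bounds must satisfy 0 < lo < hi")
        unknown = set(self.classes) - set(PERTURBATION_CLASSES)
        if unknown:
            errors.append(f"unknown perturbation classes: {sorted(unknown)}")
        errors.extend(self.perturbation.validate())
        return errors

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fragment_len_bounds"] = list(self.fragment_len_bounds)
        d["classes"] = list(self.classes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "perturbation" in d and isinstance(d["perturbation"], dict):
            d["perturbation"] = PerturbationSpec(**d["perturbation"])
        if "fragment_len_bounds" in d:
            d["fragment_len_bounds"] = tuple(d["fragment_len_bounds"])
        if "classes" in d:
            d["classes"] = tuple(d["classes"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


DYAD_COLUMNS = ["chrom", "pos", "weight", "fuzziness", "gene_id", "role"]


@dataclass
class SyntheticTruth:
    """The planted genome model; the ground truth recovery is scored against.

    ``dyads`` maps condition label -> DataFrame(chrom, pos, weight,
    fuzziness, gene_id, role); ``gene_labels`` maps gene id -> perturbation
    class ("none" for unperturbed genes); ``true_ndr`` has one row per
    (gene, condition) with the planted promoter and terminator NDR lengths.
    """

    annotation: GenomeAnnotation
    dyads: dict[str, pd.DataFrame]
    gene_labels: pd.Series
    true_ndr: pd.DataFrame  # columns: gene_id, condition, tss_ndr, tts_ndr
    config: SyntheticConfig

    @property
    def conditions(self) -> list[str]:
        return list(self.dyads)

    def genes_with_label(self, label: str) -> list[str]:
        return sorted(self.gene_labels.index[self.gene_labels == label])

    def ndr_lengths(self, condition: str, anchor: str = "tss") -> pd.Series:
        col = "tss_ndr" if anchor == "tss" else "tts_ndr"
        sub = self.true_ndr[self.true_ndr["condition"] == condition]
        return sub.set_index("gene_id")[col]

    def equals(self, other: "SyntheticTruth") -> bool:
        return (
            self.annotation.chrom_sizes == other.annotation.chrom_sizes
            and self.annotation.genes.equals(other.annotation.genes)
            and self.conditions == other.conditions
            and all(self.dyads[c].equals(other.dyads[c]) for c in self.dyads)
            and self.gene_labels.equals(other.gene_labels)
            and self.true_ndr.equals(other.true_ndr)
        )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def build_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Lay out the genome and the per-condition nucleosome landscape.

    Deterministic for a given config (the config's seed feeds a dedicated
    stream, independent from the read-sampling streams).
    """
    errors = config.validate()
    if errors:
        raise ValueError("invalid SyntheticConfig: " + "; ".join(errors))
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))

    nuc = config.nucleosome_len
    half = nuc // 2
    spacing = nuc + config.linker_len
    # small clearance at both slot ends: consecutive gene units then form a
    # quasi-continuous nucleosome array (the genome is tiled apart from NDRs)
    pad = 20

    genes_per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        genes_per_chrom[i] += 1
    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)
    }

    gene_rows = []   # (id, chrom, start, end, strand)
    dyad_rows = []   # wt dyads
    ndr_rows = []    # per-gene planted widths
    gene_idx = 0
    for ci, (chrom, n_slot) in enumerate(zip(chrom_sizes, genes_per_chrom)):
        if n_slot == 0:
            continue
        slot_len = config.chrom_length // n_slot
        # minimal footprint of one gene unit: pads + upstream pair + promoter
        # NDR + (+1 nucleosome) + terminator NDR + downstream nucleosome
        min_needed = (
            2 * pad + 2 * spacing + config.min_ndr_width + spacing
            + config.min_ndr_width + nuc
        )
        if slot_len < min_needed:
            raise SizingError(
                f"cannot fit {n_slot} genes of >= {min_needed} bp "
                f"(promoter NDR + >= 3 nucleosomes + terminator NDR) into "
                f"{chrom} of length {config.chrom_length}"
            )
        for si in range(n_slot):
            gene_idx += 1
            gid = f"g{gene_idx:04d}"
            slot_start = si * slot_len
            slot_end = slot_start + slot_len
            strand = "+" if rng.random() < 0.5 else "-"
            w_prom = int(round(max(
                config.min_ndr_width,
                rng.normal(config.ndr_width_mean, config.ndr_width_sd),
            )))
            w_term = int(round(max(
                config.min_ndr_width,
                rng.normal(config.tts_ndr_width_mean, config.tts_ndr_width_sd),
            )))
            # forward (slot-local) layout, mirrored later for "-" genes
            m2 = pad + half                    # −2 dyad
            m1 = m2 + spacing                  # −1 dyad
            tss = m1 + half + 1 + w_prom       # first position after the NDR
            down = slot_len - pad - half - 1   # downstream nucleosome dyad
            tts = down - half - w_term         # terminator NDR = [tts, tts+w_term)
            body = []
            d = tss + half
            while d + half < tts:
                body.append(d)
                d += spacing
            if not body:
                raise SizingError(
                    f"gene {gid}: no room for a +1 nucleosome between promoter "
                    f"and terminator NDRs (slot {slot_len} bp)"
                )
            local = [("-2", m2), ("-1", m1)]
            local += [("+1" if k == 0 else "body", p) for k, p in enumerate(body)]
            local += [("down", down)]
            if strand == "+":
                dyads = [(role, slot_start + p) for role, p in local]
                g_start, g_end = slot_start + tss, slot_start + tts + w_term
            else:
                mirror = lambda p: slot_start + (slot_len - 1 - p)
                dyads = [(role, mirror(p)) for role, p in local]
                g_start, g_end = mirror(tts + w_term - 1), mirror(tss) + 1
            for role, p in dyads:
                if not (0 <= p - half and p + half < config.chrom_length):
                    raise SizingError(
                        f"gene {gid}: nucleosome span outside {chrom} bounds"
                    )
                dyad_rows.append((chrom, int(p), role, gid))
            gene_rows.append((gid, chrom, int(g_start), int(g_end), strand))
            ndr_rows.append((gid, w_prom, w_term))

    annotation = GenomeAnnotation.from_intervals(chrom_sizes, gene_rows)
    wt = pd.DataFrame(dyad_rows, columns=["chrom", "pos", "role", "gene_id"])
    wt["weight"] = np.maximum(
        _gamma_weights(rng, config, len(wt)), 1e-6
    )
    wt["fuzziness"] = float(config.fuzziness_sd)
    wt = wt[DYAD_COLUMNS]

    # --- perturbation labels -------------------------------------------------
    all_genes = [g[0] for g in gene_rows]
    labels = pd.Series("none", index=pd.Index(all_genes, name="gene_id"))
    k = int(round(config.perturbed_fraction * config.n_genes))
    classes = list(config.classes)
    if k * len(classes) > config.n_genes:
        raise SizingError(
            f"perturbed_fraction {config.perturbed_fraction} x {len(classes)} "
            f"classes exceeds the {config.n_genes} available genes"
        )
    if k > 0 and classes:
        chosen = rng.choice(config.n_genes, size=k * len(classes), replace=False)
        for j, cls in enumerate(classes):
            for gi in chosen[j * k:(j + 1) * k]:
                labels.iloc[gi] = cls

    # --- mutant landscape ----------------------------------------------------
    mut = wt.copy()
    spec = config.perturbation
    strand_of = annotation.genes["strand"]
    ndr_df_rows = []
    for gid, w_prom, w_term in ndr_rows:
        label = labels[gid]
        sign = 1 if strand_of[gid] == "+" else -1  # genomic direction toward TSS
        sel = mut["gene_id"] == gid
        prom_mut, term_mut = w_prom, w_term
        if label == "occupancy":
            mut.loc[sel & (mut["role"] == "-1"), "weight"] *= spec.occupancy_fold
        elif label == "shift":
            promoter = sel & mut["role"].isin(["-2", "-1", "+1"])
            mut.loc[promoter, "pos"] += sign * spec.shift_bp
        elif label == "fuzziness":
            mut.loc[sel & (mut["role"] == "-1"), "fuzziness"] *= spec.fuzziness_factor
        elif label == "ndr_shrink":
            upstream = sel & mut["role"].isin(["-1", "-2"])
            mut.loc[upstream, "pos"] += sign * spec.ndr_shrink_bp
            prom_mut = w_prom - spec.ndr_shrink_bp
            if prom_mut <= 0:
                raise SizingError(
                    f"gene {gid}: ndr_shrink_bp {spec.ndr_shrink_bp} >= planted "
                    f"NDR width {w_prom}"
                )
        ndr_df_rows.append((gid, "wt", w_prom, w_term))
        ndr_df_rows.append((gid, "mut", prom_mut, term_mut))
    for chrom, size in chrom_sizes.items():
        pos = mut.loc[mut["chrom"] == chrom, "pos"]
        if ((pos - half < 0) | (pos + half >= size)).any():
            raise SizingError(f"perturbed nucleosome span outside {chrom} bounds")

    true_ndr = pd.DataFrame(
        ndr_df_rows, columns=["gene_id", "condition", "tss_ndr", "tts_ndr"]
    )
    return SyntheticTruth(
        annotation=annotation,
        dyads={"wt": wt.reset_index(drop=True), "mut": mut.reset_index(drop=True)},
        gene_labels=labels,
        true_ndr=true_ndr,
        config=config,
    )


def _gamma_weights(rng, config, n):
    cv = config.occupancy_dispersion
    if cv == 0:
        return np.full(n, float(config.occupancy_mean))
    shape = 1.0 / cv**2
    scale = config.occupancy_mean / shape
    return rng.gamma(shape, scale, size=n)


def _condition_stream(config: SyntheticConfig, condition: str):
    tag = int.from_bytes(
        hashlib.sha256(condition.encode()).digest()[:4], "big"
    ) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), 1, tag]))


def sample_reads(truth: SyntheticTruth, condition: str,
                 config: SyntheticConfig | None = None) -> ReadSet:
    """Draw a read set for one condition from the planted landscape.

    Each fragment: nucleosome chosen with probability proportional to its
    expected occupancy weight, dyad jittered by that nucleosome's fuzziness
    SD, fragment length drawn from the truncated normal, and either one
    single-end read of ``read_len`` on a random strand or (paired mode) the
    whole fragment emitted as one record.  A ``background_fraction`` of
    fragments is placed uniformly on the genome.
    """
    if condition not in truth.dyads:
        raise KeyError(f"unknown condition {condition!r}")
    config = config or truth.config
    rng = _condition_stream(config, condition)
    depth = int(config.depth)
    if depth == 0:
        return ReadSet.empty(paired=config.paired_end)

    dyads = truth.dyads[condition]
    chroms = list(truth.annotation.chrom_sizes)
    sizes = truth.annotation.chrom_sizes

    n_bg = rng.binomial(depth, config.background_fraction)
    n_nuc = depth - n_bg

    parts = []
    if n_nuc > 0 and len(dyads) > 0:
        w = dyads["weight"].to_numpy(float)
        idx = rng.choice(len(dyads), size=n_nuc, p=w / w.sum())
        mid = dyads["pos"].to_numpy()[idx] + rng.normal(
            0.0, 1.0, size=n_nuc
        ) * dyads["fuzziness"].to_numpy(float)[idx]
        parts.append((dyads["chrom"].to_numpy()[idx], np.rint(mid).astype(np.int64)))
    if n_bg > 0:
        lengths = np.array([sizes[c] for c in chroms], dtype=float)
        ci = rng.choice(len(chroms), size=n_bg, p=lengths / lengths.sum())
        pos = (rng.random(n_bg) * lengths[ci]).astype(np.int64)
        parts.append((np.array(chroms, dtype=object)[ci], pos))
    if not parts:
        return ReadSet.empty(paired=config.paired_end)
    chrom_arr = np.concatenate([p[0] for p in parts])
    mid_arr = np.concatenate([p[1] for p in parts])
    n = len(mid_arr)

    lo, hi = config.fragment_len_bounds
    frag_len = np.rint(_truncated_normal(
        rng, config.fragment_len_mean, config.fragment_len_sd, lo, hi, n
    )).astype(np.int64)
    f_start = mid_arr - frag_len // 2
    f_end = f_start + frag_len
    # clip fragments into chromosome bounds, preserving their length when possible
    size_arr = np.array([sizes[c] for c in chrom_arr], dtype=np.int64)
    shift = np.where(f_start < 0, -f_start, 0) + np.where(
        f_end > size_arr, size_arr - f_end, 0
    )
    f_start = np.clip(f_start + shift, 0, None)
    f_end = np.minimum(f_end + shift, size_arr)

    if config.paired_end:
        df = pd.DataFrame(
            {"chrom": chrom_arr, "start": f_start, "end": f_end,
             "strand": np.full(n, "+")}
        )
        paired = True
    else:
        strand = np.where(rng.random(n) < 0.5, "+", "-")
        rl = np.minimum(config.read_len, f_end - f_start)
        start = np.where(strand == "+", f_start, f_end - rl)
        end = start + rl
        df = pd.DataFrame(
            {"chrom": chrom_arr, "start": start, "end": end, "strand": strand}
        )
        paired = False
    df = df.sort_values(["chrom", "start", "end", "strand"], kind="stable")
    df = df.reset_index(drop=True)
    return ReadSet(df[READ_COLUMNS], paired=paired)


def write_fixture(truth: SyntheticTruth, readsets: dict[str, ReadSet],
                  out_dir) -> dict:
    """Write reads (BED), annotation (GFF3), truth tables (TSV) and config
    (YAML) to ``out_dir``; return a manifest with per-file SHA-256 checksums.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def _p(name):
        paths[name] = os.path.join(out_dir, name)
        return paths[name]

    write_gff3(truth.annotation, _p("genes.gff3"))
    write_chrom_sizes(truth.annotation.chrom_sizes, _p("chrom.sizes"))
    for condition, rs in readsets.items():
        write_bed_reads(rs, _p(f"reads_{condition}.bed"))
    for condition, df in truth.dyads.items():
        df.to_csv(_p(f"truth_dyads_{condition}.tsv"), sep="\t", index=False)
    truth.gene_labels.rename("label").to_csv(_p("truth_gene_labels.tsv"), sep="\t")
    truth.true_ndr.to_csv(_p("truth_ndr.tsv"), sep="\t", index=False)
    truth.config.to_yaml(_p("config.yaml"))

    manifest = {
        "files": {name: sha256_file(path) for name, path in sorted(paths.items())}
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
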