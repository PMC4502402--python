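# nucdyn

Detection of condition-dependent nucleosome dynamics from MNase-seq, with
promoter/terminator NDR quantification, meta-gene profiling and promoter
enrichment statistics — plus a synthetic MNase-seq generator with planted
ground truth so the whole chain can be validated end to end.

## Who this is for

Chromatin biologists and computational genomicists comparing nucleosome
landscapes between two conditions (wild type vs a mutant, untreated vs
treated) from mononucleosomal MNase-seq libraries mapped to a compact
genome (yeasts and similar). The package answers four questions:

1. **Which nucleosomes are dynamic?** Occupancy change, position shift or
   fuzziness change between conditions, at a nucleosome-level FDR.
2. **How do promoter NDRs change?** Per-gene nucleosome-depleted-region
   length at the TSS (and TTS), its delta between conditions, and the
   extreme deciles of that delta.
3. **Where does the −1 nucleosome sit?** Strand-aware meta-gene occupancy
   profiles and the average −1 nucleosome distance to the TSS per
   condition.
4. **Are the dynamics promoter-specific?** Fisher's exact enrichment of
   dynamic nucleosomes in the promoter window (−350..+50 around the TSS)
   and overlap tests between gene sets.

## Method summary

Reads are clonal-filtered (stacks of identical 5′ ends truncated by a
Poisson test at cutoff 1e−10 against the genome-wide mean λ), shifted 3′
by half the cross-correlation-estimated fragment size so each read sits on
its nucleosome dyad, expanded to a 147 bp footprint to form per-bp
occupancy, and quantile-normalized across samples. Nucleosomes are called
as occupancy local maxima above the genome mean with ≥147 bp summit
spacing; the per-bp differential signal between conditions is a two-sided
Poisson test p(b|a) = min(1, 2·min(P(X≥b), P(X≤b))) with a the reference
occupancy (floored at 0.5) and b the rounded alternative occupancy.
Matched nucleosome pairs are classified (occupancy fold ≥ 1.5, |Δsummit| ≥
10 bp, fuzziness ratio ≥ 1.3; dominance occupancy > shift > fuzziness) and
retained at Benjamini–Hochberg FDR < 0.005 using calibrated two-sample
tests on the span reads (see `docs/methods.md`). NDR length at an anchor
is the longest run of positions strictly below mean − SD of the genome
occupancy whose proximal border lies closer than 65 bp to the anchor.

## Worked example

```python
from nucdyn import NucleosomeDynamics, SyntheticConfig

model = NucleosomeDynamics.from_synthetic(SyntheticConfig(seed=1))
results = model.fit()
print(results.summary())
```

prints (exact numbers for seed 1):

```
================================================================
Nucleosome dynamics between conditions 'wt' (reference) and 'mut'
================================================================
      wt:    100000 reads (1 clonal removed), fragment size 150 bp, 3198 nucleosomes called
     mut:    100000 reads (0 clonal removed), fragment size 152 bp, 3210 nucleosomes called
----------------------------------------------------------------
dynamic nucleosomes (FDR < 0.005): 41 (1.28% of wt calls)
          position_shift: 35
          occupancy_change: 6
promoter enrichment (TSS -350..+50): OR = 12.29, p = 2.8e-11
average -1 nucleosome: 214 bp (wt) vs 209 bp (mut) upstream of TSS (shift toward TSS: 5 bp)
...
recovery of planted perturbations:
  median delta-NDR at planted shrink genes: 45 bp (unperturbed: 2 bp)
  -1 shift at planted shrink genes (per-gene): 46 bp
================================================================
```

Reading this: of 3198 wild-type nucleosomes, 41 differ significantly
between the two simulated conditions, and those are 12-fold enriched in
promoters — the perturbations were planted there. The genes planted with a
44 bp promoter-NDR shrink are recovered with a median measured shrink of
45 bp, and their −1 nucleosomes move a median ~46 bp toward the TSS.

The same chain runs from the shell:

```bash
nucdyn simulate --out fixture --seed 1        # BED/GFF3/TSV fixture + truth
nucdyn run --config run.yaml                  # full pipeline + report.json
nucdyn ndr --track occ.bedgraph --annotation genes.gff3 \
       --chrom-sizes chrom.sizes --anchor tss --out ndr.tsv
```

where `run.yaml` can be as small as `{synthetic: {}, seed: 1, out_dir: out}`.

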