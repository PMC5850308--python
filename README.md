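# paleosrna

Damage-aware small-RNA profiling for highly degraded (ancient) sequencing
libraries, with a fully synthetic, seeded data generator so that every
analysis stage can be exercised and validated end-to-end without access
to restricted sequencing data.

## The scientific problem

RNA survives in desiccated archaeological plant material far longer than
classical kinetics would suggest, and small RNAs (sRNAs, 18–25 nt) are
particularly persistent because their short length and protein
association protect them from hydrolysis. Profiling sRNA from such
material faces four linked problems that this package addresses:

1. **Postmortem damage.** Cytosine deamination converts C→U, which
   sequencing reads as C→T substitutions (or G→A when the fragment came
   from the opposite strand). A matcher that demands exact identity
   discards genuinely endogenous, damaged reads; a matcher that accepts
   arbitrary mismatches admits contamination. `paleosrna` matches reads
   exactly *or* with a single, strand-polarized deamination-consistent
   mismatch ("ancient" mode), and exactly only in "modern" mode.
2. **Authentication.** Ancient extracts are metagenomic soups. The
   endogenous proportion of a library is estimated by combining genome
   mapping with phylogenetic intersection of each read's top two database
   hits (tie-filtered lowest common ancestor), so a read counts as
   exogenous only when it fails both criteria.
3. **Count comparison without replicates.** One ancient library must be
   compared against many modern control libraries. Counts are modeled as
   an extended Poisson process whose variance is `r` times its mean, with
   `r` estimated from the cross-control variance/mean ratio. Flat-prior
   likelihood curves for the underlying mean yield 95% central intervals;
   a family is called up- or down-regulated only when the ancient and
   control intervals are disjoint.
4. **Decay kinetics.** First-order decay applied to per-seed nucleic-acid
   mass gives an RNA half-life, `T½ = T·ln 2 / ln(V₁/V₂)`, compared
   against a reference DNA half-life; GC content is binned at 0.1%
   resolution to relate base composition to survival.

Because the original sequencing data are restricted, the package ships a
negative-binomial read simulator whose defaults mirror the study design
(19 modern control libraries plus one damaged, deeper ancient library
with three planted effect families — two up-regulated, one down). The
simulator's truth tables make every pipeline claim testable.

## Worked example

Closed-form quantities from the command line:

```sh
$ paleosrna decay --t 900 --v1 65.2 --v2 4.45 --dna-half-life 350
{
  "half_life_years": 232.37831815101447,
  "degradation_fold": 1.506164614602931
}
```

With elapsed time between 600 and 900 years, modern mass 65.2 µg/seed and
ancient mass 4.45 µg/seed, the RNA half-life lies between **155 and 232
years** — RNA degrading **1.5–2.3×** faster than DNA with a 350-year
half-life.

The full synthetic pipeline (simulate → trim/size-filter → damage-aware
match → classify → endogenous content → statistics → decay/GC):

```python
from paleosrna.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig())   # default study conditions, seed 0
stages = report["stages"]
```

At the default seed this run produces (values printed from
`stages`, rounded here for display):

- prep: 100,000 ancient reads, 58.9% in the 18–25 nt window after
  adapter trimming (controls: ~17%);
- ancient composition: rRNA 70.6%, miRNA 11.5%, mRNA 11.4%, tRNA 5.7%,
  retroelements 0.24%, unassigned 0.5% (controls average 1.16% retro);
- endogenous proportion 0.903 at a planted 0.9 mixture, intersect
  accuracy 1.000;
- overdispersion `r` = 1.85 (generator truth 2.0);
- differential calls: exactly `mir159: up`, `mir319: up`, `mir396: down`
  — the three planted effects, with no false calls among 23 families;
- profile agreement: control-vs-ancient regression R² = 0.48 with all
  families, 0.998 after excluding the three called families;
- RNA half-life 154.9–232.4 yr, degradation fold 1.51–2.26;
- mean GC of ancient miRNA reads 48.6% vs 52.3% in controls (the damage
  process lowers apparent GC).

The same run is available from the shell:

```sh
paleosrna run --seed 0 --outdir results/run0   # writes report.json + report.md
```

Each stage is also exposed individually (`paleosrna simulate / prep /
match / pia / decay / gc`); see `paleosrna --help`.

## Layout

| module | role |
| --- | --- |
| `paleosrna.synthetic` | seeded reference/read/taxonomy generator with truth tables |
| `paleosrna.read_prep` | adapter trimming, 18–25 nt size filter, dereplication |
| `paleosrna.damage_match` | k-mer-indexed exact / deamination-tolerant matching |
| `paleosrna.classify` | composition profiles, miRNA family counts, target fragments |
| `paleosrna.pia` | tie-filtered LCA intersection and endogenous-content estimate |
| `paleosrna.stats` | normalization, overdispersion, likelihood intervals, calls |
| `paleosrna.decay_gc` | half-life, degradation fold, GC binning and correlation |
| `paleosrna.pipeline` / `paleosrna.cli` | orchestration, reports, command line |

See `docs/methods.md` for the statistical model, parameter defaults and
their rationale, and known limitations.
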