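# phenoseverity

Severity annotation, scoring and benchmarking for phenotype ontologies.

Rare-disease research, gene-therapy prioritisation and clinical triage all
need to know *how bad* a phenotype is, but ontologies like the Human
Phenotype Ontology (HPO) describe phenotypes without quantifying their
severity. `phenoseverity` implements a complete pipeline for producing and
auditing such severity annotations at ontology scale:

1. **Annotation** — every phenotype term is annotated with how frequently it
   *directly causes* each of ten severity-related clinical characteristics
   (intellectual disability, death, impaired mobility, physical
   malformations, blindness, sensory impairments, immunodeficiency, cancer,
   reduced fertility, congenital onset) on the vocabulary
   never / rarely / often / always, each answer with a justification.
   Annotators are pluggable callables (an LLM adapter fits this contract); a
   deterministic mock, a uniform-random annotator and a planted-truth
   simulator are bundled, so everything here runs offline.
2. **Scoring** — frequency codes F ∈ {0,1,2,3} are multiplied by integer
   severity weights W (death 6, intellectual disability 5, impaired
   mobility and blindness 4, physical malformations / sensory impairments /
   immunodeficiency / cancer 3, reduced fertility and congenital onset 1).
   The composite severity score is

       NSS = 100 · Σⱼ Wⱼ·Fⱼ / Σⱼ Wⱼ·F_max   ∈ [0, 100],

   with Σⱼ Wⱼ·F_max = 99 under the default weights. A tier-based decision
   tree additionally assigns a categorical class
   Profound > Severe > Moderate > Mild.
3. **Evaluation** — replicate-consistency rates (lenient and stringent, with
   exact chance levels 1/2 and 1/4 for pairs), truth-set recall against
   ontology branches that *must* carry a characteristic (e.g. descendants of
   "Decreased fertility" should often/always cause reduced fertility),
   an indirect-causation audit over justifications ("indirectly",
   "does not directly") with reassignment to "never", cross-characteristic
   Pearson correlations, congenital-onset proportions by ontology branch,
   depth–consistency association (Spearman, chi-square, Cramér's V), and the
   class/score concordance effect size (partial ω²).

## Worked example

```python
import phenoseverity as ps
from phenoseverity import Characteristic, Frequency

rec = ps.PhenotypeAnnotation(phenotype="HP:0002323", name="Anencephaly")
freqs = {
    "death": "always", "intellectual_disability": "always",
    "impaired_mobility": "always", "physical_malformations": "always",
    "blindness": "rarely", "sensory_impairments": "often",
    "immunodeficiency": "never", "cancer": "never",
    "reduced_fertility": "always", "congenital_onset": "always",
}
for c in Characteristic:
    rec.annotations[c] = ps.CharacteristicAnnotation(
        c, Frequency.from_word(freqs[c.value]), ""
    )
score = ps.composite_score(rec)
print(score.raw_sum, round(score.normalised, 2), ps.classify_severity(rec).label)
```

prints `70 70.71 Profound`: the weighted values (death 18, intellectual
disability 15, impaired mobility 12, malformations 9, sensory 6, blindness
4, fertility 3, congenital 3) sum to 70 of a possible 99, giving
NSS = 100·70/99 ≈ 70.71, and two Tier-1 characteristics at often/always
(death, intellectual disability) make the class Profound.

The same pipeline from the shell, on a simulated ontology with planted
truth sets:

```bash
phenosev simulate  --out-dir demo --seed 7 --terms-per-branch 20 --plant-truth
phenosev score     --annotations demo/annotations.csv --out demo/scored.csv
phenosev benchmark --annotations demo/annotations.csv \
                   --ontology demo/ontology.obo --out demo/recall.csv
```

This writes a 169-term toy ontology, 176 annotation rows (a few phenotypes
are annotated twice), a scored table (here: 78 Severe, 54 Mild, 36
Moderate, 8 Profound; mean NSS 28.93) and a recall report whose `recall`
column is 1.0 for every characteristic with a truth set — the planted
annotator answered every truth-set member often/always. Other subcommands:
`annotate`, `classify`, `consistency`, `audit-indirect`, `correlate`,
`report`.

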