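# multigate

An in-silico genetic-design-automation engine for multiplexed engineering of
*Saccharomyces cerevisiae* with modular-cloning (MoClo/Golden Gate) toolkits.

Yeast synthetic biologists build strains from standardized plasmid kits: Level-0
parts (promoters, CDSs, terminators, connectors) are joined into
transcriptional-unit (TU) cassettes by BsaI Golden Gate cloning, cassettes are
joined into multigene constructs of up to **10 TUs** inside genomic integration
vectors by BsmBI, selectable markers are exchanged through a separate BbsI
reaction (10 markers x 10 vectors = **100** locus-marker combinations), and the
finished constructs are installed at intergenic genomic loci either by
CRISPR-Cas9-assisted integration or by NotI-release gap repair directly in
yeast. `multigate` simulates every DNA-level step of that workflow so a design
can be checked before any DNA is ordered:

- **Type IIS digestion** with exact REBASE cut geometry (BsaI GGTCTC(1/5),
  BsmBI CGTCTC(1/5), BbsI GAAGAC(2/6), NotI GC^GGCCGC), producing fragments
  whose 4-nt fusion sites are normalized to the top-strand junction sequence.
- **One-pot Golden Gate assembly**: fragments still carrying a recognition site
  are treated as reaction intermediates (the thermocycler re-cuts them); the
  survivors form a directed fusion-site graph, and every distinct simple cycle
  is a circular product. A reaction is *unique* only when exactly one cycle
  exists and no fusion site is reused.
- **The kit grammar**: part types 1-8 (with 3a/3b, 4a/4b subtypes), the
  connector scheme whose 9 internal + 9 terminal cassette configurations
  (**18** prebuilt cassettes) cover every assembly size from 2 to 10 TUs,
  marker swapping, and colony-color screening prediction from sfGFP/mScarlet
  dropout features.
- **Gap-repair planning**: NotI release of homology-armed fragments, a
  suffix/prefix overlap graph (>= 20 bp exact homology), and a *unique*
  Hamiltonian path requirement from the vector's 5' arm to its 3' arm, plus
  junction colony-PCR amplicon prediction.
- **gRNA-tRNA array design**: per-fragment PCR primers whose tails encode the
  spacer and the positional BsaI fusion site, simulated PCR and one-pot
  assembly into the CRISPR backbone, with spacer validation (20 nt, no internal
  Type IIS/NotI site, genome-unique protospacer with an NGG PAM).
- **Integration-locus selection**: intergenic windows in which every position
  is > 1 kb from any start codon and > 0.5 kb from any stop codon
  (strand-aware), genome-unique Cas9 targets ranked from the window center,
  ~500 bp homology arms, and a longest-shared-repeat diagnostic (either
  orientation) for screening co-installed parts against recombination.

A deterministic fixtures module generates a 96-plasmid toy kit and a ~50 kb toy
genome with 10 planted integration loci, so the whole pipeline runs with no
external data.

## Worked example

```python
from multigate import (FixtureConfig, generate_toy_genome, generate_toy_kit,
                       load_enzymes, plan_level2, swap_marker,
                       predict_screen_color)

enzymes = load_enzymes()
config = FixtureConfig(seed=17)
genome = generate_toy_genome(config)
kit = generate_toy_kit(config, genome)          # 96 entries

# assemble 10 spacer cassettes into the first integration vector (BsmBI)
spacers = kit.by_category("spacer")
chain = [next(e for e in spacers
              if e.metadata["position"] == p and e.metadata["terminal"] == (p == 10))
         for p in range(1, 11)]
vector = kit.by_category("integration_vector")[0]
product = plan_level2(chain, vector, enzymes)
print("product size:", len(product.sequence.bases), "bp")
print("junctions:", product.junctions)
print("colony color:", predict_screen_color(product, "ecoli"))

# add a URA3 marker by BbsI swap
ura3 = next(e for e in kit.by_category("marker_cartridge")
            if e.metadata["marker"] == "URA3")
selectable = swap_marker(vector, ura3, enzymes)
print("selectable vector:", len(selectable.sequence.bases), "bp")
```

prints

```
product size: 3188 bp
junctions: ['AACC', 'ACAG', 'AGGA', 'ATTC', 'CACG', 'CCTA', 'CGAA', 'CTAC', 'GACT', 'GAGG', 'GCTT']
colony color: white
selectable vector: 2186 bp
```

The 11 junctions are the ten connector fusion sites plus the terminal
connector closing the circle into the vector; `white` means both mScarlet
dropout cassettes were replaced, which is exactly what the red/white colony
screen selects for.

The same operations are available from a shell:

```bash
multigate make-fixtures --seed 17 --out fx
# kit: 96 entries; genome: 50690 bp, 10 planted loci
multigate validate-kit --kit fx/kit
multigate plan-level2 --kit fx/kit --tus 10 --out product.gb
# 10-TU product, 3188 bp
multigate scan-loci --genome fx/genome.fasta --gff fx/genome.gff3 --out-bed w.bed
# 10 window(s), 10 candidate locus/loci
```

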