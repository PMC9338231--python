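# flymplex

In-silico multiplex PCR species identification for five tephritid fruit
flies of economic importance in southern Africa — *Ceratitis capitata*,
*C. cosyra*, *C. quilicii*, *C. rosa* and *Bactrocera dorsalis* — plus a
pipeline for designing such panels from a species-labelled alignment.

## The problem

These five flies are quarantine pests of export fruit. Immature stages
intercepted in consignments cannot be identified morphologically, and COI
barcoding cannot separate the cryptic pair *C. rosa* / *C. quilicii*. A
published multiplex PCR assay solves this with five species-specific
primer pairs in the opsin Rh4 region, each amplifying a product of a
distinct size, so a single agarose gel lane identifies the species:

| species       | forward / reverse primer             | amplicon |
|---------------|--------------------------------------|---------:|
| *C. capitata* | Opsin4_capitata_F / _R               | 327 bp   |
| *C. cosyra*   | Opsin4_cosyra_F / _R                 | 183 bp   |
| *C. quilicii* | Opsin4_quilicii_F / _R               | 128 bp   |
| *C. rosa*     | Opsin4_rosa_F / _R                   | 249 bp   |
| *B. dorsalis* | Opsin4_dorsalis_F / _R               | 676 bp   |

`flymplex` implements the computational readout chain of this assay and
the design workflow behind it:

* **insilico_pcr** — mismatch-tolerant, IUPAC-aware primer-binding search
  on both strands under a policy (total mismatches `m`, plus a stricter
  budget inside the 3'-terminal window, default `(2, 5, 0)`), and
  exhaustive amplicon prediction over all plus×minus site pairs of the
  whole panel, so cross-amplification artifacts are predicted, not ignored.
* **gel_sim** — a virtual 2 % agarose gel: migration log-linear in
  fragment size, bands merged when closer than Δlog₁₀ = 0.04.
* **identify** — band-size species calling with the duplex tie-break: the
  *C. quilicii* pair sits in an intergenic region and can cross-amplify in
  related species, so a 128 bp band co-occurring with a larger diagnostic
  band is discounted and the larger band identifies the specimen.
* **thermo** — nearest-neighbor melting temperatures (unified DNA/DNA
  parameter set, entropic salt correction), GC, 3'-anchored dimer and
  hairpin screens.
* **panel_design** — the design pipeline: discriminatory-window scan of a
  species-labelled alignment, candidate enumeration anchored on diagnostic
  SNPs in the 3'-terminal five bases, specificity and dimer screening, and
  selection of a gel-resolvable amplicon-size ladder.
* **fixtures** — deterministic synthetic templates and alignments with the
  assay-relevant structure (embedded primer cassettes at the declared
  spacings, duplex variants, mutation injection, implanted diagnostic SNP
  clusters).

## Worked example

```sh
flymplex fixtures --species all --seed 1 --out-dir demo
flymplex identify demo/fixtures.fasta --out-dir demo/run
```

prints

```
                  lane     status  species  diagnostic_size discounted_bands notes
capitata_fixture_seed1 identified capitata              327                -
  cosyra_fixture_seed2 identified   cosyra              183                -
quilicii_fixture_seed3 identified quilicii              128                -
    rosa_fixture_seed4 identified     rosa              249                -
dorsalis_fixture_seed5 identified dorsalis              676                -
```

and exits 0 (all lanes identified; exit 2 would mean an unidentified lane,
exit 3 a band in a no-template control). Each row is one gel lane: the
single predicted product matched its species' declared size, which is the
identification. `demo/run/` holds the amplicon table (TSV/BED), the lane
table, and an auditable `calls.json` with the tool version, panel hash and
the full effective configuration. `flymplex gel demo/fixtures.fasta`
renders the corresponding virtual gel with the 100 bp ladder.

The same chain is available as a library:

```python
from flymplex import load_panel, simulate_multiplex, make_lanes, call_species
from flymplex.fixtures import FixtureSpec, synth_duplex_template

panel = load_panel("builtin:table1")
dup = synth_duplex_template(panel.entry("cosyra"), panel.entry("quilicii"),
                            FixtureSpec(seed=7))
(lane,) = make_lanes(simulate_multiplex(panel, [dup]))
call = call_species([b.size for b in lane.bands], panel)
# call.species == "cosyra", diagnostic_size == 183, discounted_bands == (128,)
```

This is the duplex case: the lane shows 183 bp and 128 bp, the 128 bp
cross-amplification band is discounted and the larger product makes the
call.

Panel design runs from an aligned FASTA with `species|record` headers:

```sh
flymplex design alignment.fasta --out-dir design
```

writing a loadable `panel.yaml`, a design report and a rejection log.

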