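# marado

Identification of **maradolipids** (6,6′-di-*O*-acyltrehaloses) and
**lysomaradolipids** (single-acyl trehalose lipids) from UHPLC–drift-tube
ion-mobility–MS data acquired with alternating-energy (AllIons/DIA)
fragmentation. These glycolipids occur exclusively in the stress-resistant
dauer stage of *Caenorhabditis elegans*; because there are almost no
authentic standards and no spectral libraries for them, their identification
rests on combining orthogonal evidence — exact mass, referenced Kendrick mass
defect, retention time, collision cross section and correlation-filtered DIA
fragments.

The package is aimed at analytical chemists and lipidomics bioinformaticians
who want the full cascade as tested, reusable code, plus a ground-truthed
synthetic-data generator that emulates the acquisition so that every stage is
testable without instrument data.

## The method

**Kendrick filtering.** On the CH₂-rescaled Kendrick scale,

```
KM   = m/z × 14 / 14.015650
KMD  = KM − ⌊KM⌋
RKMD = (KMD − KMD_ref) / 0.013399
```

members of a homologous lipid series share the KMD, and each double bond
(one H₂ deficiency, Kendrick defect 0.013399) moves the referenced KMD to the
integer −d. With the anchor KMD_ref = 0.6094 (the [M+FA−H]⁻ formate adduct of
the saturated 32-carbon maradolipid), any feature whose RKMD is within ±0.1 of
an allowed integer is a class candidate.

**CCS.** Drift-tube arrival times convert to collision cross sections
Ω (Å²) through the Mason–Schamp equation, either from a stepped-field
regression (t_d vs 1/V) or from a single-field calibration
t_A = β·(√μ/|z|)·Ω + t_fix fitted on tune-mix reference ions.

**DIA fragment assignment.** Without precursor isolation, a fragment is
accepted only if its extracted ion chromatogram — taken in the precursor's
drift-time window (±1 ms) and m/z window (±0.025 Da) — correlates with the
precursor EIC with Pearson r > 0.9 over the elution region. Diagnostic head
fragments [trehalose−H₂O−H]⁻ (m/z 323.0984) and [trehalose−2H₂O−H]⁻
(m/z 305.0878) flag diacyl species when they co-elute; the first alone flags
lyso species.

**Trendlines.** Within a series (class, double-bond count, adduct), CCS is
linear and RT typically quadratic in the total acyl carbon number; candidates
must sit on the trendlines fitted through standards (≤2 % RT, ≤0.4 % CCS).

Annotations are graded on the Metabolomics Standards Initiative scale:
level 1 needs a standard match on m/z + RT + CCS, level 2 fragment or
trendline evidence, level 3 is m/z-only.

## Worked example

```python
from marado import parse_lipid_name, adduct_mz, theoretical_fragments
from marado.kendrick import kendrick_values

lipid = parse_lipid_name("Mar(14:0/16:0)")
mz = adduct_mz(lipid.mass, "[M+FA-H]-")
print(lipid.formula, f"{mz:.4f}")        # C42H78O13 835.5424
kv = kendrick_values(mz)
print(f"{kv.kmd:.4f} {kv.rkmd:+.2f}")    # 0.6095 -0.00  (saturated: RKMD at 0)
for f in theoretical_fragments(lipid, "[M+FA-H]-"):
    print(f"{f.label:<16} {f.mz:9.4f}")
```

gives the full negative-mode catalogue, including the two neutral losses of an
unsymmetric diacyl species and the diagnostic head fragments:

```
[M-H]-             789.5370
[M-14:0(COOH)]-    561.3280
[FA(14:0)]-        227.2017
[M-16:0(COOH)]-    533.2967
[FA(16:0)]-        255.2330
[Tre-H2O-H]-       323.0984
[Tre-2H2O-H]-      305.0878
```

The end-to-end cascade on a synthetic run (the ten authentic standards planted
at their reference RT/CCS plus ten off-grid decoy features):

```bash
marado simulate --seed 1 --decoys 10 --frames-out frames.csv \
    --features-out features.csv --manifest-out manifest.csv
marado identify features.csv --frames frames.csv --out annotations.csv
```

```
             features_in: 20
              after_rkmd: 10
         after_rt_window: 10
     after_library_match: 10
  with_fragment_evidence: 9
        standard_matched: 10
     trendline_supported: 10
               annotated: 10
```

All ten planted species are annotated (all at MSI level 1, matched to their
standard); every decoy is rejected by the RKMD filter. `marado screen`
reports the diagnostic-fragment co-elution hints and `marado trendlines` the
fitted series models; `marado --show-config` prints every default parameter.

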