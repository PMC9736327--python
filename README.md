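# cavlipid

Sequence- and spectroscopy-side analysis of caveolin–lipid interaction.

Caveolin-2 is a monotopic membrane protein whose association with
cholesterol-containing bilayers is read out through several complementary
experiments: sequence motifs that predict cholesterol recognition,
hydropathy scans that predict membrane-favorable segments, far-UV circular
dichroism (CD) of the protein's secondary structure, steady-state
fluorescence (binding titrations, anisotropy, FRET, quenching), and
differential scanning calorimetry (DSC) of thermal stability.  `cavlipid`
implements the numerical pipeline for all of these as one package:

| module | what it does |
| --- | --- |
| `cavlipid.motifs` | gap-consensus scanning for CRAC `(L/V)-X1–5-(Y/F)-X1–5-(K/R)`, CARC `(K/R)-X1–5-(Y/F)-X1–5-(L/V)`, and the caveolin-binding motif (CBM) `Φxxxx­ΦxxΦ` (Φ ∈ {F, W, Y}); overlap reports between motif classes |
| `cavlipid.hydropathy` | Wimley–White interfacial free-energy profiles (windowed sum, default window 19), membrane-favorable segment calling, disorder-profile summarization |
| `cavlipid.cd` | mean residue ellipticity conversion, θ222/θ208 coiled-coil ratio, "w" vs "v" spectral-shape classification, non-negative least-squares basis deconvolution |
| `cavlipid.fluorescence` | G-factor and anisotropy, hyperbolic binding fits `y = baseline ± P1·x/(Kd + x)`, FRET efficiency `E = 1 − F_DA/F_D`, quenching curves |
| `cavlipid.dsc` | linear chemical-baseline subtraction, Tm and calorimetric/van 't Hoff enthalpy extraction, two-state fits |
| `cavlipid.synth` | seeded generators for every input kind, whose defaults encode the bundled study conditions |
| `cavlipid.pipeline` / `cavlipid.cli` | a YAML-configured multi-stage runner and a `cavlipid` command-line interface |

Coordinates are 1-based and inclusive throughout; a `numbering_offset` maps
peptide fragments onto full-length numbering.  Binding x-axes are μM, CD
ellipticity is machine mdeg (converted to deg·cm²·dmol⁻¹ on request), DSC
heat capacity is kJ·mol⁻¹·K⁻¹, and hydropathy is kcal·mol⁻¹ per window
(negative = favorable membrane-interface partitioning).

## Worked example

The caveolin-2 fragment 77–88 carries a CBM and a CARC that share the
aromatic anchor Y85:

```bash
printf '>cav2_frag\nFEISKYVMYKFL\n' > frag.fasta
cavlipid scan-motifs --fasta frag.fasta --offset 77
```

```
sequence_id	motif_class	start	end	subsequence	anchors
cav2_frag	CBM	77	85	FEISKYVMY	F77/Y82/Y85
cav2_frag	CARC	81	88	KYVMYKFL	K81/Y85/L88
```

The same numbers from Python, together with a hydropathy scan of the
full-length sequence and a binding fit of a generated titration:

```python
from cavlipid import fluorescence as fl, hydropathy as hp, motifs as mt, synth
from cavlipid.datasets import cav2_alpha
from cavlipid.sequence import ProteinSequence

frag = ProteinSequence("cav2_frag", "FEISKYVMYKFL", numbering_offset=77)
(carc,) = mt.scan(frag, mt.carc_pattern())
print(carc.start, carc.end, carc.anchor_string(frag))
# 81 88 K81/Y85/L88

profile = hp.compute_profile(cav2_alpha(), window_length=19)
for seg in hp.call_segments(profile, threshold=0.0, min_centers=2):
    print(seg.start, seg.end, round(seg.mean_dg, 2))
# 70 71 -0.07
# 73 127 -3.81
# 148 150 -0.41

art = synth.generate(synth.GeneratorConfig(seed=7, scenario="anisotropy_titration"))
fit = fl.fit_hyperbolic(art.data)
print(round(fit.kd, 4), round(fit.baseline, 4), round(fit.plateau, 4))
# 0.48 0.21 0.17
```

## Command-line interface

`cavlipid --help` lists all subcommands: `scan-motifs`, `hydropathy`,
`segments`, `disorder-summary`, `cd-ratio`, `cd-shape`, `cd-deconv`,
`fit-binding`, `anisotropy`, `fret`, `dsc-analyze`, `simulate`, and `run`
(YAML-configured pipeline).  See `docs/methods.md` for model assumptions,
parameter defaults, and numerical choices.
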