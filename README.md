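# eecfold

A toolkit for studying protein folding through entropy–enthalpy
compensation and side-chain hydrophobicity rules:

* **residue_model** — classification of the hydrophobic portion of each
  amino-acid side-chain, the hydrophobic-blocking (RB) group {D, N, S, P, G},
  and a derived, symmetric 20×20 lateral-attraction verdict table
  (overridable from a plain-text matrix file).
* **ss_predict** — rule-based secondary-structure prediction (E/H/T/C) from
  sequence: attraction graphs at sequence separations 2–4, turn nucleation
  by runs of ≥2 blocking residues, proline strand termination, and
  strand/helix attraction-density scoring with helix precedence.
* **evaluate** — segment-level coverage (recall) and success rate
  (precision) against reference annotations (STRIDE/DSSP-style letters are
  folded on ingest), turn composition, and hydrophobic
  fraction/involvement statistics. Undefined ratios are reported as `NA`,
  never 0 or 1.
* **thermo** — the compensation arithmetic: hydrogen-bond swap enthalpy
  (break two peptide–water bonds, form one backbone bond plus one
  water–water bond), hydration-shell entropy release, and
  ΔG = ΔH − TΔS with a spontaneity flag.
* **gibbs_surface** — a conformational Gibbs free-energy functional on
  union-of-balls (CPK) models: numerically estimated union volume,
  boundary area and per-hydrophobicity-class areas, a pairwise Coulomb
  term, finite-difference force decomposition (packing / aqueous /
  expansion), and a gradient-descent relaxer with backtracking.
* **dock2d** — two-rule 2-D docking of labelled surface patches:
  maximize hydrophobic pixel overlap subject to a minimum number of
  donor–acceptor contacts, by exhaustive search over rotations and integer
  translations of the mirrored facing patch.
* **harness** — FASTA / PDB-subset / patch (PGM/CSV) / ball-model I/O,
  flat key-value configuration, a click CLI, and deterministic synthetic
  fixture generators (sequences with planted motifs, ball clusters,
  complementary patch pairs with a recorded transform).

## CLI

A single `eecfold` entry point with subcommands; every subcommand accepts
`--config` (flat `key = value` file), `--seed`, and `--log-level`.
Reports are 1-based inclusive; logs go to stderr.

```bash
eecfold classify LKGPT             # residue classes
eecfold classify --table           # full 20x20 verdict table (CSV)
eecfold predict-ss --fasta in.fasta --fmt fasta
eecfold predict-ss --fasta in.fasta --explain
eecfold evaluate --manifest manifest.tsv --out report.tsv
eecfold thermo --n-waters 12
eecfold gibbs --model cluster.model
eecfold relax --model cluster.model --step 0.3
eecfold dock2d patch_a.pgm patch_b.pgm --rotation-step 90 --min-hb 3
eecfold simulate sequences --out-dir fixtures/ --count 10 --seed 1
```

Config keys are namespaced per parameter set, e.g.

```
predictor.min_strand_len = 4
predictor.strand_density_min = 0.6
thermo.temperature = 310
gibbs.omega = 0.05 -0.05
```

## Notes on defaults

* The water–water hydrogen-bond energy default (6.18 kcal/mol) is a
  calibrated value, chosen so the swap bookkeeping reproduces the
  2.70 kcal/mol worked value from the three sourced bond magnitudes; it is
  exposed and documented as calibrated, not sourced.
* Surface chemical potentials, the per-volume electron potential and the
  Coulomb constant in `gibbs_surface` have documented toy defaults; they
  are required configuration for any quantitative use.
* Docking thresholds ("several" donor/acceptor contacts → `min_hb = 3`
  within a Chebyshev pixel radius of 1) are declared defaults,
  configurable per call.
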