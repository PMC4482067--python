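# rnapivot

Detection and quantification of pivot points — localized hinges — in large
ribosomal RNAs, from pairs of atomic-coordinate files representing two
conformational states (for example, elongation-factor-G bound versus unbound
ribosomal subunits, or classical versus ratcheted 70S states).

## Who this is for

Structural biologists comparing crystallographic or cryo-EM models of the
same rRNA in two states.  Global superpositions of such pairs mix every
motion together; the interesting signal — where a helix reorients and by how
much — lives in short, localized hinges.  `rnapivot` isolates these by
superimposing a short **rigid stem** proximal to each candidate hinge, which
decouples the local motion from global rearrangements such as intersubunit
rotation and head swivel.

## The method

Each candidate helix is divided into three parts: a rigid stem, the pivot
(the motif where one strand's deviation from the partner state begins to
grow), and the final loop that completes the structure.

1. **Global control.** Both states are superimposed over all paired heavy
   atoms (least-squares Kabsch fit with iterative outlier rejection).  The
   resulting RMSD is the variation a local motion must exceed to be
   meaningful; it also drives a screen for particularly mobile helices.
2. **Stem superposition.** For each catalog helix, only the stem atoms are
   superimposed (a single complete Watson–Crick pair already provides ≥ 30
   heavy atoms, the minimum the package accepts).  The post-fit stem RMSD is
   the comparison's local noise floor.
3. **Deviation profile and pivot call.** Along the helix path (stem → loop,
   on each strand) the per-residue deviation between states is the mean
   displacement of the phosphodiester backbone atoms
   {P, O5′, C5′, C4′, C3′, O3′}.  The pivot is the first residue whose
   deviation exceeds max(1 Å, 2 × stem residual) and stays above it for two
   consecutive residues.  For a pure hinge of angle θ the deviation of a
   residue at mean distance *r* from the hinge axis is the chord
   2 sin(θ/2)·*r*.
4. **Magnitude.** The motion is quantified as the displacement of a
   designated final-loop tip residue after stem superposition, in Å.
5. **Motif class.** Base pairs are detected geometrically (C1′–C1′ in
   8.5–11.5 Å, ≥ 2 donor–acceptor contacts < 3.5 Å, near-coplanar bases) and
   the pivot site is classified with precedence
   G-U wobble > non-canonical pair > bulge > three-way junction.
6. **Cascade.** Aligning at an upstream pivot's stem versus each downstream
   helix's own stem separates carried motion from local motion; the ratio
   (amplification) and a contact network (physical contact under 5 Å,
   induced motion above 1.5× amplification) summarize the coupling.

Because deposited ribosome structures are too large to bundle, the package
ships a synthetic generator (`rnapivot.synthetic`) producing idealized
A-form duplexes (rise 2.81 Å, twist 32.7°/bp) with a hinge of known angle,
axis and motif, plus exact ground truth — every stage is validated against
the analytic chord 2 sin(θ/2)·*r*.

## Worked example

```sh
python examples/01_simulate_and_detect.py
```

prints (exact displacement varies with the noise seed):

```
true pivot residue      : 7
detected pivot residue  : 8
tip displacement        : 8.00 A  (analytic chord 7.64 A)
stem residual after fit : 0.720 A
motif at pivot          : unassigned
```

A 10° hinge after base pair 6 with 0.3 Å coordinate noise is localized to
within one residue of the truth; the measured tip displacement matches the
analytic chord up to noise, and the sub-angstrom stem residual confirms the
stem was rigid.  The other examples cover deviation profiles
(`02`), motif classification (`03`), cascade/network analysis (`04`) and
mobile-helix screening (`05`).

For real structure pairs the same pipeline runs from the shell:

```sh
rnapivot global-rmsd --input-a stateA.cif --input-b stateB.cif
rnapivot detect --input-a stateA.cif --input-b stateB.cif \
    --stem-catalog my_catalog.tsv --output-dir out
rnapivot cascade --input-a stateA.cif --input-b stateB.cif \
    --stem-catalog my_catalog.tsv --upstream h28
```

Stem catalogs are TSV files
(`helix_id  chain  stem_ranges  path_ranges  tip_residue`, inclusive ranges
such as `10-17,40-47`); best-effort catalogs for E. coli-numbered 16S/23S
pivot helices ship under `src/rnapivot/data/` as starting points.
`rnapivot simulate` writes a synthetic pair plus its catalog and ground
truth.

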