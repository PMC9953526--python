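# Methods

## Scope and model

The package analyses *pre-computed* trajectories of short GAG chains. It
never runs molecular dynamics and does no periodic-boundary arithmetic:
trajectories are assumed post-processed (solute whole, counterions wrapped
near the solute), which is the form in which MD packages emit analysis
trajectories. Coordinates are in Å throughout; residues are numbered
1-based from the non-reducing end.

The glycosidic bridge is modelled as a single oxygen atom, owned by the
residue that contributes the anomeric carbon and named O1; files that name
it O4/O3 on the acceptor residue are resolved by the convention table. The
φ/ψ torsion quadruples are O5–C1–O1–C4′ / C1–O1–C4′–C5′ for
hexosamine(β1→4)uronic-acid linkages (type 1) and O5–C1–O1–C3′ /
C1–O1–C3′–C4′ for uronic-acid(β1→3)hexosamine linkages (type 2). Writing
the torsions over the single bridging oxygen plus the next-residue carbons
is the standard heavy-atom definition for these linkages; a notation that
lists the bridge twice under two names denotes the same four atoms.

## Descriptor definitions and numerical choices

**RMSD.** Unweighted, all solute atoms, best-fit superposition by the SVD
(Kabsch) algorithm with the reflection branch removed (the smaller singular
vector is sign-flipped when det < 0, so the rotation is always proper).
Reference = first stored frame. The trajectory literature is split on
whether "RMSD to the initial structure" implies fitting; fitted and
unweighted is the common tool default and is what this package computes,
stated here explicitly. Flexibility is reported as the variance (and sd) of
the series; no block averaging.

**Dihedrals.** Signed, IUPAC convention (clockwise positive looking along
the central bond), cis = 0, wrapped to [−180, 180) with trans reported as
−180 so that binning is single-valued. Collinear or coincident defining
atoms raise.

**Cremer–Pople puckering.** Atom order O5, C1…C5; centred coordinates; the
mean-plane normal is R′×R″ from the standard weighted sums; q2/φ2 from the
m = 2 Fourier projections (with the conventional minus sign on the sine
sum), q3 = 6^(−1/2) Σ (−1)^(j−1) z_j; Q = √(q2²+q3²),
θ = atan2(q2, q3) ∈ [0, 180], φ ∈ [0, 360). Under this convention the
4C1 chair of a β-D-pyranose sits at θ ≈ 0. `build_ring` inverts the
transform on a regular hexagon traversed clockwise (seen from +z); because
the inserted displacements contain only m = 2, 3 harmonics, the hexagon
plane *is* the Cremer–Pople mean plane and the round trip is exact to
machine precision — this identity is the generator's and the tests' anchor.

**Conformer classification.** Sector map, fully configurable: θ < 45° →
4C1; θ > 135° → 1C4; in the equatorial band, a named skew conformer when φ
is within ±15° of its meridian, else *other*. The 2SO and 1S3 meridians are
150° and 210°: these follow by evaluating the transform on the idealised
skew patterns (named atom above the four-atom plane, counter-atom below)
under this package's atom ordering. Published sector choices differ between
groups, which is why the map is configuration, not a constant. Amplitude
floor: Q < 0.1 Å flags φ/θ as degenerate (φ is numerically undefined as
Q → 0) and labels the frame *other*.

**MVEE.** Khachiyan barycentric ascent on the determinant-maximisation
dual with Wolfe–Atwood away steps (linear convergence), tol = 10⁻⁴,
iteration cap 10⁵ (non-convergence raises), convex-hull pre-reduction
(only hull vertices can support the ellipsoid). The returned shape matrix
is rescaled so all input points are inside; the volume is then within
O(tol) of the optimum. Degenerate (coplanar/collinear) point sets raise
with the advice to jitter or reduce dimension.

**Histograms.** EED × volume: 50 × 50 bins over the data range (the
literature this follows prints no bin widths; these are declared artifact
defaults). φ × ψ: fixed 5° bins over [−180, 180)². Cell values are
probabilities (count / total).

**Hydrogen bonds.** Donors/acceptors are O and N; the donor hydrogen is
inferred covalently (nearest O/N within 1.2 Å). A bond requires heavy-atom
distance < 3.0 Å AND D–H–A angle at the hydrogen > 135° — the usual
defaults of MD H-bond tools, with the angle vertex stated explicitly
because tools differ. The residue-pair matrix sums per-pair frame
fractions (both donor→acceptor directions folded), so a cell may exceed 1
when several simultaneous bonds exist; the diagonal is within-residue.
Explicit hydrogens are mandatory; their absence is an error, not a silent
zero. For long trajectories the solute–water bond count is evaluated on a
deterministic frame stride (≤ ~2000 frames) — it is a mean, not a
per-frame series.

**Counterion contacts.** Group centre of mass is mass-weighted (standard
element masses); contact = any ion within the kind cutoff (4.0 Å carboxyl,
4.2 Å sulfate); the per-kind summary is mean ± population sd across groups
of that kind. "No ions in the topology" raises — it is a different
statement from "never in contact".

**Electrostatic repulsion.** E = k Σ q_i q_j / r_ij over atom pairs
belonging to two different charged groups, k = 332.0522 kcal·Å·mol⁻¹·e⁻²,
vacuum dielectric, no distance cutoff. Intra-group pairs are excluded: the
quantity is the repulsion *between* charged groups; including intra-group
self-terms would add a large conformation-insensitive constant. Charges
are never hard-coded: they come from a PQR charge column or a
(residue, atom) → charge JSON map.

**Bimodality (comparison table).** One- vs two-component Gaussian mixtures
(seeded, deterministic), flagged bimodal when ΔBIC > 10, both weights
≥ 0.15 and the means are ≥ 2 pooled sd apart; Sarle's bimodality
coefficient is reported alongside. An exact Hartigan dip statistic needs a
specialised algorithm not available in the installed stack; a decisive
mixture-model comparison is the standard, easily-auditable alternative and
its thresholds are explicit parameters. Neither number claims to match any
visual judgement of bimodality.

## The synthetic generator

The generator's job is statistical structure, not physics: no force field,
no sterics beyond clearance checks, no solvent structure. Each frame is
built independently (no kinetics): rings via the Cremer–Pople inverse at a
pucker state drawn from the planted categorical distribution (state
geometries: chairs Q = 0.55 Å at θ = 5°/175°, skews Q = 0.65 Å at
θ = 90°, φ = 150°/210°); chains assembled by natural-extension (NeRF)
placement with the planted φ/ψ drawn from Gaussian mixtures (optionally
one shared per-frame component across linkages — a global two-state
switch); substituents from fixed torsion templates; 0.03 Å Gaussian jitter
added last.

Planted hydrogen bonds and waters use *probe pockets*: the donor–acceptor
pair is moved ~7 Å off the two residues' ring-centroid midpoint, in the
per-frame direction (from a fixed 64-direction candidate sphere) with the
largest clearance from all atoms placed so far. Inside the pocket the pair
is collinear — acceptor, then the donor oxygen at 2.7 Å (flagged) or 3.6 Å
(unflagged) with the hydrogen pointing at or away from the acceptor — so
both detector criteria hold exactly when flagged and both fail when not,
with margins (0.3 Å, 0.9 Å, 135°) that the jitter (≤ 0.05 Å allowed)
cannot bridge. Only chemically "free" atoms (hydroxyl O, amide N,
carbonyl O) may be moved; ring, linkage and charged-group atoms are
protected. Every remaining polar hydrogen is re-aimed, per frame, at the
candidate direction maximising the smallest angle to all acceptors within
3.3 Å, so template geometry cannot create incidental bonds. Ions sit at
0.85 × cutoff from their group's centre of mass (contact frames) or ≥ 60 Å
away (non-contact); synthetic charges are bookkeeping values (−0.5 e per
carboxylate oxygen, −1/3 e per terminal sulfate oxygen), documented as
synthetic, not force-field charges.

Preset planted tendencies follow the qualitative study picture: GalNAc
stays 4C1 (more mobile at chain ends), GlcA keeps one dominant chair with
small minor populations, IdoA splits ~60/40 between chairs; DS carries the
correlated two-state linkage switch, CS chains a 92/8 unimodal-plus-minor
mixture; planted ion-contact rates are the study's per-type contact
fractions (carboxyl 0.019–0.023, sulfate 0.014–0.015).

**What passing tests show — and what they don't.** Recovery tests prove
the *analysis* is correct: each estimator returns the planted rate within
binomial error. They say nothing about force fields, solvent, kinetics, or
the absolute conformational populations of real GAGs; frames are i.i.d.,
exchange dynamics are not modelled, and descriptor values on synthetic
chains (e.g. absolute volumes, which include the probe-pocket atoms ~7 Å
off the chain) are not comparable to experimental or MD magnitudes.

## Problem sizes used in validation

Analytic and oracle checks run at their natural sizes (200 ring round
trips, 10⁴ dihedral quadruples, 50 ellipsoid clouds of 12 points).
Parameter recovery uses one 10⁴-frame dp4 run; the study-shaped run uses
all 18 preset oligomers at 2000 frames each — ensembles large enough that
the 3-binomial-se recovery bands are a few tenths of a percent wide, while
a full validation pass stays in the minutes range on one CPU.

## Known limitations

* PDB/PQR/DCD/XTC only (parsing via MDAnalysis); no mmCIF or AMBER-native
  formats; no water analysis beyond the solute–water H-bond count.
* The pucker sector map is this package's default, not a reproduction of
  any specific published range table; change it via configuration when
  matching other work.
* dp2 chains give geometrically weak R_gyr bimodality even under a planted
  two-state linkage switch (a single linkage rotation barely changes the
  compactness of two rigid rings); two-state shape detection is meaningful
  from dp4 up.
* Planted waters require one free hexosamine hydroxyl each, which caps the
  plantable water count at the number of hexosamine residues.
* The comparison table's bimodality flag is threshold-based; borderline
  mixtures (small minor weights, small separations) are deliberately left
  unflagged.
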