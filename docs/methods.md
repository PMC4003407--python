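# Methods

## Geometry: projection, frames, unrolling

The medial axis is an ordered polyline with cumulative arc length
`cum_s` (μm); validity requires ≥ 2 vertices, no repeated consecutive
vertices, and `cum_s` reproducing pairwise Euclidean distances exactly.
SWC input is reconstructed by following parent pointers from the single
root (row order is not trusted; the radius column is ignored), and any
branching node is rejected: the sonification is defined along a single
unbranched path. All coordinates are μm end to end; no unit metadata is
honored.

A spine's axial coordinate *s* is the arc length of its orthogonal
projection onto the polyline, interpolated within segments; ties in
distance are resolved toward smaller *s* for determinism. The angular
coordinate needs a twist-free moving frame. Frenet frames are unusable
here (undefined where curvature vanishes, flip at inflections), so frames
are rotation-minimizing, propagated vertex-to-vertex by the
double-reflection method with a final re-orthogonalization against the
local tangent to absorb floating-point drift. The first normal is a
user-chosen reference direction (default (1, 0, 0)) orthogonalized against
the first tangent; a reference parallel to the first tangent is an error.
Between vertices the normal is linearly interpolated, re-orthogonalized,
and renormalized — adequate because consecutive frames differ by small
angles on any reasonably sampled axis. θ = atan2(r·b, r·n) in degrees,
mapped to [0, 360), right-handed about the tangent. Consequences that the
tests verify: (s, θ) is invariant under rigid motions when the reference
is co-rotated; on a planar curve with an out-of-plane reference the normal
stays fixed; frames agree with small-step parallel transport at 10×
resolution to < 0.1°. A spine inserting exactly on the axis has no defined
angle; θ is set to 0 with a logged warning rather than an error.

## Mapping conventions

Category intervals are left-closed, right-open. The printed threshold
notations ("< 0.20", "0.20 − 0.40", "> 0.60") overlap at the boundary
values, so one convention had to be fixed: a volume of exactly 0.20 μm³ is
mf, a length of exactly 2 μm is trumpet. Dynamics map to MIDI velocities
32/64/96/120 (pp/mf/f/ff) — unspecified upstream; equally spaced and
distinguishable. Timbres map to General MIDI programs 45 (pizzicato
strings), 0 (acoustic grand), 56 (trumpet), 40 (violin).

Pitch uses C major from a configurable root (default MIDI 60): 7 wedges →
C4..B4, 14 → two octaves, and the 4-wedge variant — whose exact notes are
not documented anywhere — is realized as C4, E4, G4, C5 (root triad plus
octave, maximally discriminable by ear). In bidirectional mode with *n*
intervals the first *n*/2 ascend on the left channel and the last *n*/2
mirror them on the right, the peak degree shared by the last ascending and
first descending interval (with 8 intervals: Do Re Mi Fa | Fa Mi Re Do).
This is the only mirror convention consistent with equal-count symmetric
halves and with 15° → Do-left / 345° → Do-right. Angles outside [0, 360)
are normalized modulo 360 with a warning (numerical wrap tolerance), not
rejected. Length may drive dynamics only when volume mapping is off;
length never drives dynamics and timbre simultaneously.

Scanning speed defaults to "auto" with a 60 s target duration — slow
enough to separate notes at realistic densities, short enough to hold
attention; note duration is a constant 0.25 s (listeners cannot reliably
compare similar note lengths, so duration carries no data). The drone
("basal sound") plays only from t = 0 until the first note, not between
notes: program 89 pad, note 36, velocity 20, parameters invented for an
unobtrusive background. MIDI files are format 1 at 120 BPM and 480
ticks/quarter (≈1 ms quantization), giving byte-reproducible output; MIDI
channels are allocated one per (program, pan) pair — skipping the
percussion channel — so chords mixing timbres or stereo sides never
interact, and pan is controller 10 (0/64/127 = left/centre/right). With no
MIDI library in the dependency set, the writer and the reader used for
round-trip checks are implemented here against the SMF specification.

## Synthetic patterns

The generator draws `n = round(density × length)` spines (Poisson counts
by flag; the fixed default keeps counts exactly reproducible), positions
uniform on [0, L], and angles either uniform on [0, 360) or helical,
θ = (360 s/P + jitter) mod 360 with Gaussian jitter. Defaults are the
study conditions of interest: a 100 μm segment at 1.41 spines/μm (the
young-segment density; the old case uses 1.03), lognormal marks with
σ = 0.6 / 0.8 calibrated so mean length ≈ 1.4 μm and mean volume
≈ 0.35 μm³ (only segment means are reported upstream, so lognormal — the
standard right-skewed choice for spine morphometrics — was fixed here),
insertion radius 0.5 μm as a shaft-radius proxy, and a 10 μm helix period
(no published value; one turn per analysis window of the kind used for
these dendrites). All draws come from a single seeded generator in a fixed
order (positions, angles, lengths, volumes), so a seed reproduces a table
byte-for-byte. Insertion points are reconstructed in the same
rotation-minimizing frames the unroller uses, which is what makes the
generator/unroller round trip exact on a straight axis (< 1e−3 μm,
< 0.1°).

What the generator does **not** emulate: curved shafts with varying
diameter, anisotropic optical distortion, missed or merged spines from
segmentation, correlation between position and spine size, and
branch-point effects. Passing tests therefore demonstrate correctness of
the transforms and calibration of the tests under these idealized
conditions, not performance on raw confocal reconstructions.

## Pattern tests

Helical vs random: the statistic is max over candidate periods P of the
mean resultant length of phases (θᵢ − 360 sᵢ/P), which is 1 for a perfect
helix and O(1/√n) for random angles, and is invariant under global
rotation of all θ. The candidate set is a *frequency* grid f = 1/P from
1/L to density/2 at spacing 1/(2L), followed by golden-section refinement
(40 iterations) inside the bracket around the grid argmax. The spacing
matters: the resultant-length peak has half-width ≈ 1/L in frequency, so a
coarse or log-spaced period grid can straddle the peak and lose it; the
1/(2L) grid guarantees a grid point inside the main lobe, and refinement
then attains the peak (statistic 1.0 to machine precision on a jitter-free
helix, at the true period). The null permutes θ against s — exact under
exchangeability — and every permutation is maximized by the identical
grid+refinement procedure, so the search over periods cannot inflate
significance. At least 10 spines are required.

Category clustering: statistic = mean nearest-neighbour distance in s
among target-category spines (minimum of left/right gaps after sorting;
end spines use their single gap); the null permutes labels. One-sided:
small distances indicate clustering. Both tests report add-one
Monte-Carlo p-values, p = (1 + #extreme)/(1 + n_perm), with "extreme"
oriented toward the alternative (≥ for periodicity, ≤ for clustering);
the smallest attainable p is 1/(1 + n_perm), and a fixed seed fixes p.

## Problem sizes and numerical choices

Test and acceptance workloads use 100 μm segments at n ≈ 141: calibration
of each test over 200 null seeds at 199 permutations, and power for a
20°-jitter helix over 100 seeds at 999 permutations (the acceptance script
reports a 30-seed rate). 199 permutations give an exact Monte-Carlo level
of 0.045 at α = 0.05 under the add-one rule; calibration is asserted
within a 3σ binomial band around α. Axis polylines carry ≥ 100 vertices
(1000 by default) and generated axes are rescaled so the discrete arc
length equals the request; CSV floats are written with 6 significant
digits, which round-trips byte-identically. Degenerate inputs are handled
explicitly: empty spine lists yield empty scores and NaN morphometric
means (with a warning), an empty score still writes a valid MIDI file, and
equal onsets are kept as chords ordered by spine id.

## Known limitations

The unrolling convention (frame construction, angular origin) is this
package's own documented choice — upstream descriptions of the transform
do not specify one — so absolute θ values are comparable only within a
fixed reference direction; all statistics used here are rotation-invariant.
The clustering observation the test formalizes has no published
ground-truth value, so only calibration and constructed-extreme behavior
are verifiable. Audio (WAV) synthesis, engraved notation and interactive
playback are out of scope; the MIDI file plus event list are the
authoritative outputs.
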