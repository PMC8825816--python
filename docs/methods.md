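# Methods

## Problem and model

`octcyst` decides whether a single retinal OCT B-scan (rows = depth,
columns = lateral position) contains cystic fluid. Cysts appear as dark
pockets inside brighter tissue, so the decision is built entirely from
*directional intensity changes* of the local mean map, never from layer
or fluid segmentation.

For an image with intensities `X[i,j]` (normalized to [0, 255]) the
local mean over a `(2a+1) x (2b+1)` window is

    A[i,j] = (1 / (2a+1)(2b+1)) * sum_{p=i-a..i+a, q=j-b..j+b} X[p,q]

and the difference maps are

    dv[i,j] = A[i-1,j]   - A[i+1,j]      vertical
    dl[i,j] = A[i-1,j-1] - A[i+1,j+1]    down-right diagonal
    dr[i,j] = A[i-1,j+1] - A[i+1,j-1]    down-left diagonal
    df[i,j] = A[i+2,j]   - A[i-2,j]      wide-offset vertical

Positions where any operand's window leaves the image are undefined
(NaN); padding is never used because it would fabricate transitions at
the borders. All local-maximum conditions are *strict* (`>`); plateaus
produce no maximum, so perfectly flat edges are invisible by design.

### Phase 1 — denoising

A 3x3 median filter (reflected edges). OCT speckle is multiplicative
and a small median window suppresses it without displacing edges;
`median_kernel = 1` disables denoising.

### Phase 2 — boundary-pixel determination

Seeds `V`: strict vertical local maxima of `dv` with `dv > thv` and
`dv > 0` (bright above, dark below — the entrance point of a potential
cyst). Diagonal sets `L` and `R`: the analogous three conditions on
`dl` along the down-right diagonal and `dr` along the down-left
diagonal. For every seed `(i,j)` two `s x t` patches are formed, over
columns `j-t..j-1` (left) and `j+1..j+t` (right) and rows `i+1..i+s`;
a patch is accepted when it contains strictly more than `num` members
of `L` (left) or `R` (right). Patches are clipped at the image
boundary and `num` is not rescaled, so edge seeds need the same
absolute evidence.

**Patch row anchoring.** Patches sit strictly *below* the seed row.
The geometric argument: the fluid pocket and its two descending walls
lie below the entrance point, so the diagonal-change pixels of a true
cyst spread over the rows beneath the seed. A straight horizontal
layer interface — present in every B-scan — instead concentrates all
of its diagonal-change pixels on the seed's own row: with the default
`t = 11`, `num = 10` a patch that included the seed row would collect
exactly 11 members from any sufficiently sharp interface and certify a
cyst in every scan. Excluding the seed row makes straight interfaces
structurally inert while leaving curved cyst walls (which cross up to
`s + t - 1` diagonals inside a patch) clearly above threshold. A
`centered` alignment is available via `DetectionParams.patch_align`
for comparison.

**Threshold `thv`.** No published value exists for the significance
threshold, so the default is relative: `thv = 0.08 x` the intensity
range of the denoised image (about 15 units on a full-range 8-bit
scan). A relative threshold keeps behavior stable across acquisition
brightness; an absolute `thv` can be fixed explicitly and the sweep
harness supports calibration.

### Phase 3 — shadow detection and candidate removal

Vessels cast dark vertical stripes that create spurious boundary
pixels. Per column the tracker computes `m_th`, the smallest of the
column's top `floor(alpha * m)` mean values, and finds `Q_j`: the
*bottom-most* row where `|df|` has a strict local maximum along the
column, `df < 0` (dark-to-light moving upward) and `A[i-2,j] >= m_th`
(the region above is genuinely bright). In an unshadowed column `Q_j`
sits at the lower edge of the bright RPE band; under a shadow that
band fails the brightness bar and `Q_j` jumps to a higher structure or
vanishes. The `Q` track is segmented wherever consecutive columns jump
by more than `jump_thr` rows or flip between present and absent; a
segment is flagged as shadow when it has no transitions at all or its
median `Q` is displaced from the global median (the unshadowed
baseline) by more than `jump_thr`. This run-based reading of the
consecutive-column jump rule flags whole shadow regions, tolerates a
column whose transition disappears inside a deep shadow, and cannot be
toggled out of phase by an isolated noisy column. It assumes shadows
cover a minority of columns; a scan that is mostly shadow would invert
the baseline.

`|df|` local maxima are used (rather than a literal local maximum of
the negative-valued `df`), since a signed maximum in the negative
regime would select the *weakest* transitions. `floor(alpha*m)` is
clamped to at least 1. `m_th` is computed per column, following the
per-column loop of the procedure.

Candidates whose seed column lies within `shadow_margin` columns of a
flagged column are discarded (default margin = `t`: a candidate whose
patch could overlap a shadow is suspect). The scan is labeled *cystic*
when at least `min_candidates` (default 1) survive — one accepted
patch already certifies `num + 1` boundary pixels.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `a`, `b` | 1, 1 | mean-window half-height/width (3x3 window) |
| `s`, `t` | 11, 11 | patch rows / columns |
| `num` | 10 | patch acceptance count (strictly exceeded) |
| `thv` | 0.08 x range | significance threshold, intensity units |
| `alpha` | 0.08 | brightness quantile for `m_th` |
| `jump_thr` | max(10, ceil(0.05 m)) | shadow-boundary jump, rows |
| `median_kernel` | 3 | denoising window, px |
| `shadow_margin` | `t` | candidate discard distance, columns |
| `min_candidates` | 1 | cystic-label threshold |

## Synthetic phantoms

The generator renders what the detector consumes: a layered
reflectivity profile, dark elliptical fluid pockets, multiplicative
vessel shadows below a stated row, a small Gaussian point-spread blur
(sigma 0.8 px), and multiplicative Gaussian speckle
(`pixel * (1 + sigma * z)`, default sigma 0.05). The default
`dme_like` preset (100 x 256): vitreous at 30, bright inner band rows
20-28 at 165, tissue at 120 reached through an 8-row taper, a thin
bright RPE band rows 74-78 at 220, dark background at 30, and one wide
flat cyst (semi-axes 10 rows x 24 columns, interior 35) at (50, 128).

Two rendering choices matter and are deliberate:

* **Band interfaces are never two-level steps.** A perfect step makes
  the two straddling `dv` values exactly equal, a tie no real scan
  exhibits, and the strict local-maximum rule then resolves edges only
  through noise. Sharp interfaces get a one-row intermediate value;
  the moderate inner-band/tissue interface is tapered over 8 rows so
  its vertical gradient stays below the default `thv`, as reflectivity
  between the inner complexes fades gradually in real scans.
* **The RPE band is thinner than `floor(alpha*m)` rows.** The
  brightness cutoff `m_th` must land *below* the RPE values (on the
  next-brightest structure) for the transition test to certify the RPE
  lower edge. Real scans satisfy this automatically (hundreds of rows
  against a 15-20 px band); at `m = 100` and `alpha = 0.08` it
  requires an RPE band under 8 rows.

What the phantoms do **not** emulate: Rayleigh/gamma speckle statistics
(only the second-order structure the detector reads is matched), foveal
curvature, intra-tissue texture, vendor-specific contrast. Passing
tests therefore demonstrate the algorithmic mechanisms — seed/patch
voting, shadow tracking, false-positive suppression — not clinical
accuracy; published sensitivity/specificity on real scans (SE
0.79-0.93, SP 0.39-0.8 depending on parameters and dataset) can only be
reproduced with the corresponding clinical datasets.

On these phantoms the batch evaluation (25 cystic / 25 shadow-only
scans, speckle 0.05) reaches SE = SP = 1.0 with the shadow filter and
SP = 0.0 without it — synthetic cysts are unambiguous and every shadow
stripe produces removable false candidates, so the filter's effect
appears in pure form. A consequence of the patch geometry worth noting:
the `s,t = 13` patch is a superset of the `s,t = 11` patch at fixed
`num`, so growing the window can only add candidates; the documented
"smaller window, higher SE" trend can therefore appear on phantoms only
as equality (detection saturates at both sizes), never as a strict
increase.

## Numerical and degenerate-input choices

* Intensities are rescaled to [0, 255] float on load (by dtype range);
  multi-channel input is collapsed by channel average with a warning.
* Undefined map positions are NaN; every comparison with NaN is False,
  so undefined neighbors never certify a maximum.
* Mean maps are accumulated by shifted adds (no FFT/cumsum), matching
  naive summation to ~1e-12 of a 255-scale value.
* Ties: strict inequalities everywhere; the descending sort behind
  `m_th` needs no tie rule because only the k-th order statistic is
  used.
* Images smaller than 7x7 (no offset-2 interior) are rejected with the
  required minimum in the message; even median kernels, `num < 0`,
  `num >= s*t`, `alpha` outside (0,1) all raise before any image work.
* Undefined SE/SP ratios (empty positive or negative class) are
  reported as NaN with a warning, never imputed.

## Problem sizes

Tests and the acceptance script run on 100 x 256 phantoms, batches of
up to 50 scans, and 50 random 30 x 30 images for oracle equivalence;
the full suite completes in well under a minute on one core.

## Known limitations

* The cystic/non-cystic rule from surviving candidates
  (`min_candidates`) is an explicit surrogate; the source method's
  exact rule is implicit.
* Shadow-run classification assumes shadows are a minority of columns.
* Strict maxima miss genuinely flat (plateau) edges.
* Whether seeds must also belong to `L`/`R` is answered "no"; every
  column is searched (no subsampling).
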