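# Methods

## Model and definitions

The data are M phased, bi-allelic haplotype sequences over N aligned sites
(a 0/1 matrix), optionally with a non-decreasing genetic coordinate g[0..N)
in cM. An **L-long match** between the query z and panel haplotype x is a
site interval [b, e) with z[b,e) = x[b,e), a mismatch (or sequence end) at
b−1 and at e, and e − b ≥ L (site mode) or g[e−1] − g[b] ≥ L (cM mode).
The engine reports exactly this set, each match once, sorted by
(haplotype, start). All coordinates are 0-based, half-open.

## Syllabic panel

Sites are grouped into syllables of B consecutive sites; site kB+j occupies
bit j of syllable k (earliest site = least-significant bit), and the final
syllable is zero-padded past N. With the low bit first, the mismatch
closest to a run on its left is the *highest* set bit of the XOR of the
boundary syllables and on its right the *lowest* set bit, which is what the
single-site refinement uses. Raw syllable values for B ≤ 64 are held as
uint64; any B ≥ 1 is accepted, with wider syllables falling back to
arbitrary-precision integers (the contract is exact equality and XOR, not a
machine width).

Each syllable column is coordinate-compressed: r_k is the sorted list of
distinct raw values, and the stored code is the rank in r_k. Columns are
packed, compressed and discarded one at a time, so the raw matrix is never
fully resident. The compression ratio ρ = Mn / Σ_k |r_k| ≥ 1 measures how
much linkage disequilibrium collapses the panel (ρ = M when all haplotypes
are identical, 1 when every column's values are all distinct).

## Index structures

- **Positional prefix arrays** a_0..a_n: a_k lists haplotypes by ascending
  reversed prefix x[0,k) (syllable k−1 most significant), ties in input
  order; a_0 is the identity, and each a_{k+1} follows from a_k by one
  stable sort on the column codes (keys bounded by |r_k| ≤ M).
- **Prefix hash arrays**: h_i[k] = Σ_{j<k} (x_i[j]+1)·BASE^j mod MOD, so
  agreement of two sequences over syllables [j, k) is tested by comparing
  (h[k] − h[j]) mod MOD. These replace the divergence and virtual-extension
  arrays of site-level PBWT query algorithms.

Hash parameters: MOD is the Mersenne prime 2^61 − 1, so hash values fit
64-bit words; BASE is drawn uniformly from [2^20, MOD−2] from a stored seed
at build time and persisted with the index, so query-time hashes are
computed with identical parameters and the base cannot be anticipated by an
adversarial input. A single hash function is used; a false equality on one
interval comparison has probability about (k−j)/MOD < n/MOD (≈ 3·10⁻¹⁶ at
n = 10⁶), and the suite's oracle-equivalence sweeps would surface any
collision. The +1 shift keeps code 0 from hashing identically across
positions.

Persistence is a single versioned container: magic bytes, a JSON header
(dimensions, hash parameters, haplotype ids, SHA-256 of the payload), then
the raw little-endian array bytes. Loading verifies magic, version and
checksum; the writer embeds no timestamps, so identical inputs produce
byte-identical files (tested via the CLI).

## Query algorithm

1. **Encoding.** The query is syllabified like a panel row; its code at
   syllable k is the rank of its raw value in r_k, or the sentinel |r_k|
   when absent. The sentinel orders the query above all panel values at
   that column regardless of the absent value's true rank; this cannot
   misplace any detection, because a detected window consists only of
   syllables where the query *equals* some panel value, and columns where
   it matches nobody can only shift its position within a block of
   sequences it matches nowhere — both scan directions stop at the first
   hash mismatch either way.
2. **Virtual insertion.** t_k = number of panel sequences whose reversed
   prefix over [0,k) sorts ≤ the query's (the query sits below ties; the
   convention is arbitrary for correctness but makes t testable). Each t_k
   is a binary search over a_k; one comparison inspects syllable k−1
   directly and, on a tie, hash-binary-searches the most significant
   differing syllable. The search range is bounded below by s_{k−1} − 1,
   where s_k is the start of the query's longest reverse-prefix match at
   syllable k: s_k is non-decreasing in k, and any comparison must be
   decided at or after s_k − 1 (an earlier-deciding sequence would itself
   be a longer match), so the bound is exact, and hash equality over the
   restricted range implies full prefix equality. s_k is recomputed each
   step from the two sorted neighbours of t_k.
3. **Windows.** In site mode every qualifying match fully contains
   l = ⌊(L−B+1)/B⌋ syllables (an interval may waste up to B−1 sites in
   each flanking partial syllable), defined for L ≥ 2B−1, i.e.
   B ≤ ⌈L/2⌉; smaller L raises a threshold error naming the minimum. In cM
   mode the per-syllable window w_k is the smallest w such that a match
   containing only the full syllables [k−w, k), maximally extended into
   both flanking partial syllables, would already span ≥ L cM; any
   qualifying match whose last full syllable is k−1 therefore contains
   ≥ w_k full syllables and is detected at k. Syllables where even w = k
   fails are never tested.
4. **Scanning.** At each syllable k the haplotypes whose window [k−w_k, k)
   agrees with the query's form a contiguous block around t_k (reversed
   prefix order sorts longer agreements closer). The scan walks up from
   t_k − 1 − up_on and down from t_k + down_on while the window hashes
   match, where up_on/down_on count ongoing (already reported) matches:
   once found, a match stays immediately adjacent until it ends, and no
   undetected sequence can sort closer to the query than an ongoing one
   (its longer agreement would have been detected earlier), so the skip is
   sound — including in cM mode where w_k varies. A match emitted at k is
   extended to its maximal full-syllable run [b, e): rightward (and, when
   the detected window is not flush with the run start, leftward) by
   probing compressed codes linearly for up to 10 syllables, then
   hash-binary-searching — cheap for the typical short match, O(log n) for
   the rare long one. Ends are tallied so the match stops being skipped
   from syllable e+1 on, the first syllable at which its window test fails.
   An optional "scout" mode binary-searches each new block's far end before
   iterating it; output is identical (tested) and it is off by default.
5. **Refinement.** For run [b, e): if b = 0 the match starts at site 0,
   else at (b−1)B + (highest set bit of z̄[b−1] XOR x̄[b−1]) + 1; if e = n
   it ends at N, else at eB + (lowest set bit of z̄[e] XOR x̄[e]), clamped
   to N (padded bits are zero on both sides and never differ, but the
   clamp keeps the contract explicit). The match is reported iff the
   refined span reaches L sites, or g[end−1] − g[start] ≥ L cM.

## Parameters

| parameter | default | meaning |
|---|---|---|
| B | 128 (CLI; 64 the usual alternative) | sites per syllable; memory shrinks ≈ B-fold, minimum usable L grows as 2B−1 |
| L | user-set | match cutoff, sites or cM; site mode requires L ≥ 2B−1 |
| MOD | 2⁶¹−1 | hash modulus (fixed) |
| hash seed | 0 | derives BASE; persisted in the index |
| linear-probe depth | 10 syllables | extent probing before switching to hash binary search |

## Synthetic data

Tests and self-checks use a mosaic-of-founders generator: F founder
haplotypes i.i.d. Bernoulli(0.5); each panel haplotype copies one founder
at a time, re-drawing its source with per-site probability `switch_rate`
(default 0.005 → ~200-site blocks) and flipping sites at `mut_rate`
(default 0.001). This reproduces the one property the method exploits —
repeated local haplotype blocks, so |r_k| ≪ M — but is *not* a
population-genetic model: no coalescent genealogy, recombination hotspots,
allele-frequency spectrum, phasing or genotyping error. Passing tests
therefore demonstrate algorithmic exactness (engine ≡ brute force on
LD-structured input), not robustness to real-data error modes, which the
exact-match problem excludes by definition. Queries are random or
noisy-copy backgrounds with segments copied verbatim from named haplotypes;
planted coordinates are advisory and every assertion takes ground truth
from the brute-force matcher, since chance agreement extends plants.
Synthetic maps accumulate spacings mean·((1−jitter) + jitter·Exp(1)), so
jitter interpolates between a uniform and a fully exponential map. All
generators are integer-seeded numpy `default_rng` streams.

The study-scale sweeps in `tests/test_acceptance.py` use a fixed-seed
200 × 10,000 panel (6 founders, switch 0.005, flip 0.001) at B = 16 with
100 queries (50 carrying plants of length L−1, L, 2L, 5L; 50 random),
L = 64 sites, repeated in cM mode with a jittered map averaging 3/64 cM per
site and L = 3 cM — sizes chosen so the whole suite runs in well under a
minute on one core while still exercising thousands of matches per mode.

## Numerical and degenerate-input choices

- Stable sorting everywhere; ties in prefix arrays always resolve to input
  order, making every structure bit-reproducible across runs.
- The tie side of virtual insertion (query below equal sequences) is a
  convention; both scan directions stop at the first hash mismatch, so
  correctness does not depend on it.
- B > N builds a single padded syllable; all-identical panels, M = 1
  panels, and empty match sets are all exercised in tests.
- Site-mode L arriving as a float via the CLI must be integral; cM-mode L
  is a float and uses the span between the first and last matched site.

## Known limitations

- Exact matching only: a single genotyping or phase error splits a match
  (mismatch-tolerant extension is out of scope).
- cM mode cannot see a match containing no full syllable; such a match can
  reach L cM only across a map gap comparable to L itself. Site mode is
  immune by the L ≥ 2B−1 guard.
- The brute-force verifier is O(MN) per query and is intended for panels up
  to ~10³ × 10⁵; `--verify` at biobank scale is not practical.
- Multi-allelic sites, missing genotypes and unphased data are rejected at
  ingest, not coerced.
- Hash collisions are possible in principle; their probability is bounded
  above and no collision has been observed in any oracle-equivalence sweep.
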