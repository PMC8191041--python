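"""Six-mer pore model: expected current levels for canonical and BrdU k-mers.

A pore model maps every 6-mer occupying the nanopore to the mean and spread
(both pA) of the ionic current it produces.  BrdU-for-thymidine substitution
shifts the current of every 6-mer that contains the analogue; those variants
are keyed with the letter ``B`` in place of the substituted ``T`` so that any
combination of substituted/unsubstituted thymidines inside one 6-mer has its
own entry.

The default model is synthetic and generated once from a fixed seed: canonical
means are drawn uniformly on 60-120 pA with spreads on 1-2 pA, and each
B-containing variant shifts its canonical counterpart by a N(0, 3 pA) draw
whose magnitude is clamped to at least 1.5 pA.  This keeps the analogue
detectable but noisy, which is the regime the detection network is trained
for.  Models may also be loaded from / written to a plain TSV
(``kmer<TAB>mean<TAB>sd``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

K = 6
ALPHABET = "ACGTB"  # B = BrdU (substituted thymidine)
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_POW5 = 5 ** np.arange(K - 1, -1, -1, dtype=np.int64)
N_EXTENDED = 5 ** K  # 15625 k-mers over ACGTB
N_CANONICAL = 4 ** K  # 4096 k-mers over ACGT

DEFAULT_MODEL_SEED = 210609


class PoreModelError(ValueError):
    """Raised for invalid, incomplete, or inconsistent pore-model tables."""


def kmer_to_code(kmer: str) -> int:
    """Base-5 integer code of a k-mer over the ACGTB alphabet."""
    if len(kmer) != K:
        raise PoreModelError(f"k-mer {kmer!r} does not have length {K}")
    try:
        return int(sum(_CODE[c] * p for c, p in zip(kmer, _POW5)))
    except KeyError as exc:
        raise PoreModelError(f"k-mer {kmer!r} contains invalid character {exc.args[0]!r}") from exc


def code_to_kmer(code: int) -> str:
    digits = []
    for p in _POW5:
        digits.append(ALPHABET[(code // p) % 5])
    return "".join(digits)


def _digits(codes: np.ndarray) -> np.ndarray:
    """(n, K) array of base-5 digits for each code."""
    return (codes[:, None] // _POW5[None, :]) % 5


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode an ACGT(B) string as integer symbols; reject anything else."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for c, i in _CODE.items():
        out[arr == ord(c)] = i
    if (out < 0).any():
        bad = chr(arr[int(np.argmax(out < 0))])
        raise PoreModelError(f"sequence contains non-ACGT character {bad!r}")
    return out


@dataclass
class PoreModel:
    """Current-level table over the extended (ACGTB) 6-mer space.

    ``mean`` and ``sd`` are dense arrays indexed by base-5 k-mer code; entries
    are NaN where the table has no row.  Canonical completeness (all 4096
    ACGT 6-mers) is an invariant; analogue coverage of every T-containing
    6-mer is checked at validation.
    """

    k: int = K
    mean: np.ndarray = field(default_factory=lambda: np.full(N_EXTENDED, np.nan))
    sd: np.ndarray = field(default_factory=lambda: np.full(N_EXTENDED, np.nan))

    # -- mapping-style views -------------------------------------------------
    @property
    def levels(self) -> dict[str, tuple[float, float]]:
        """Canonical 6-mer -> (mean pA, sd pA)."""
        return {
            code_to_kmer(c): (float(self.mean[c]), float(self.sd[c]))
            for c in np.flatnonzero(~np.isnan(self.mean))
            if "B" not in code_to_kmer(c)
        }

    @property
    def brdu_levels(self) -> dict[str, tuple[float, float]]:
        """B-containing 6-mer -> (shifted mean pA, sd pA)."""
        return {
            code_to_kmer(c): (float(self.mean[c]), float(self.sd[c]))
            for c in np.flatnonzero(~np.isnan(self.mean))
            if "B" in code_to_kmer(c)
        }

    def level(self, kmer: str) -> tuple[float, float]:
        code = kmer_to_code(kmer)
        m = self.mean[code]
        if np.isnan(m):
            raise PoreModelError(f"pore model has no entry for k-mer {kmer!r}")
        return float(m), float(self.sd[code])

    def canonical_level_array(self) -> tuple[np.ndarray, np.ndarray]:
        """(4096,) mean/sd arrays indexed by base-4 canonical k-mer code."""
        codes = np.arange(N_EXTENDED, dtype=np.int64)
        dig = _digits(codes)
        canonical = (dig < 4).all(axis=1)
        base4 = (dig[canonical] * (4 ** np.arange(K - 1, -1, -1))).sum(axis=1)
        mean4 = np.full(N_CANONICAL, np.nan)
        sd4 = np.full(N_CANONICAL, np.nan)
        mean4[base4] = self.mean[codes[canonical]]
        sd4[base4] = self.sd[codes[canonical]]
        return mean4, sd4

    def validate(self) -> None:
        codes = np.arange(N_EXTENDED, dtype=np.int64)
        dig = _digits(codes)
        canonical = (dig < 4).all(axis=1)
        defined = ~np.isnan(self.mean)
        missing = canonical & ~defined
        if missing.any():
            names = [code_to_kmer(int(c)) for c in np.flatnonzero(missing)[:5]]
            raise PoreModelError(
                f"pore model is missing {int(missing.sum())} canonical k-mer(s), "
                f"e.g. {', '.join(names)}"
            )
        if (self.sd[defined] <= 0).any():
            bad = int(np.flatnonzero(defined & (self.sd <= 0))[0])
            raise PoreModelError(f"non-positive sd for k-mer {code_to_kmer(bad)!r}")
        # every T-containing canonical k-mer needs >= 1 analogue variant
        has_b = (dig == 4).any(axis=1)
        variant_codes = codes[has_b & defined]
        vdig = _digits(variant_codes)
        vdig[vdig == 4] = 3  # B -> T gives the canonical counterpart
        covered = np.zeros(N_EXTENDED, dtype=bool)
        covered[(vdig * _POW5).sum(axis=1)] = True
        has_t = (dig == 3).any(axis=1) & canonical
        uncovered = has_t & ~covered
        if uncovered.any():
            name = code_to_kmer(int(np.flatnonzero(uncovered)[0]))
            raise PoreModelError(
                f"{int(uncovered.sum())} T-containing k-mer(s) lack an analogue "
                f"variant, e.g. {name}"
            )


def default_pore_model(seed: int = DEFAULT_MODEL_SEED) -> PoreModel:
    """The package's synthetic pore model, reproducible from its fixed seed."""
    rng = np.random.default_rng(seed)
    codes = np.arange(N_EXTENDED, dtype=np.int64)
    dig = _digits(codes)
    canonical = (dig < 4).all(axis=1)

    mean = np.full(N_EXTENDED, np.nan)
    sd = np.full(N_EXTENDED, np.nan)
    mean[canonical] = rng.uniform(60.0, 120.0, size=int(canonical.sum()))
    sd[canonical] = rng.uniform(1.0, 2.0, size=int(canonical.sum()))

    # analogue variants: canonical counterpart + clamped Gaussian shift
    has_b = ~canonical
    bdig = _digits(codes[has_b])
    bdig[bdig == 4] = 3
    counterpart = (bdig * _POW5).sum(axis=1)
    shift = rng.normal(0.0, 3.0, size=int(has_b.sum()))
    sign = np.where(shift >= 0, 1.0, -1.0)
    shift = sign * np.maximum(np.abs(shift), 1.5)
    mean[has_b] = mean[counterpart] + shift
    sd[has_b] = sd[counterpart]

    model = PoreModel(mean=mean, sd=sd)
    model.validate()
    return model


def load_pore_model(path) -> PoreModel:
    """Read a ``kmer<TAB>mean<TAB>sd`` TSV and validate completeness.

    Canonical rows use ACGT; analogue rows spell the substituted thymidine(s)
    as ``B``.  Missing canonical k-mers, non-positive spreads, and T-containing
    k-mers without any analogue variant are hard errors.
    """
    mean = np.full(N_EXTENDED, np.nan)
    sd = np.full(N_EXTENDED, np.nan)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise PoreModelError(f"{path}:{lineno}: expected 3 tab-separated columns")
            kmer, m, s = parts
            code = kmer_to_code(kmer)
            try:
                mval, sval = float(m), float(s)
            except ValueError as exc:
                raise PoreModelError(f"{path}:{lineno}: non-numeric level for {kmer!r}") from exc
            if sval <= 0:
                raise PoreModelError(f"{path}:{lineno}: non-positive sd for k-mer {kmer!r}")
            mean[code] = mval
            sd[code] = sval
    model = PoreModel(mean=mean, sd=sd)
    model.validate()
    return model


def write_pore_model(model: PoreModel, path) -> None:
    """Write the TSV form; canonical rows first, then analogue rows, sorted."""
    defined = np.flatnonzero(~np.isnan(model.mean))
    rows = sorted(
        (code_to_kmer(int(c)), float(model.mean[c]), float(model.sd[c])) for c in defined
    )
    with open(path, "w") as fh:
        for brdu_pass in (False, True):
            for kmer, m, s in rows:
                if ("B" in kmer) == brdu_pass:
                    fh.write(f"{kmer}\t{m:.6f}\t{s:.6f}\n")


def expected_levels(
    sequence: str, brdu_mask: np.ndarray, model: PoreModel
) -> tuple[np.ndarray, np.ndarray]:
    """Expected (mean, sd) current per k-mer position of a masked sequence.

    ``brdu_mask`` holds one boolean per thymidine in ``sequence`` (in order of
    appearance); ``True`` marks that T as substituted by BrdU.  Position ``i``
    of the output uses the 6-mer starting at ``i``, looked up with analogue
    levels whenever the mask marks any T inside that window.
    """
    if len(sequence) < K:
        raise PoreModelError(f"sequence shorter than k-mer length {K}")
    symbols = encode_sequence(sequence)
    if (symbols == 4).any():
        raise PoreModelError("sequence must be ACGT; substitution is expressed via brdu_mask")
    t_pos = np.flatnonzero(symbols == 3)
    mask = np.asarray(brdu_mask, dtype=bool)
    if mask.shape != t_pos.shape:
        raise PoreModelError(
            f"brdu_mask length {mask.size} != thymidine count {t_pos.size}"
        )
    symbols = symbols.copy()
    symbols[t_pos[mask]] = 4  # mark substituted T as B
    n = len(sequence) - K + 1
    codes = np.zeros(n, dtype=np.int64)
    for j in range(K):
        codes += symbols[j : j + n] * _POW5[j]
    means = model.mean[codes]
    if np.isnan(means).any():
        bad = int(codes[int(np.argmax(np.isnan(means)))])
        raise PoreModelError(f"pore model has no entry for k-mer {code_to_kmer(bad)!r}")
    return means, model.sd[codes]
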