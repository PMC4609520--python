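"""Seeded generator of synthetic clinical datasets.

The real clinical corpus behind the method is not deposited, so downstream
modules are exercised on synthetic data with the same structure: a latent
disease per record drives a one-hot ICD-10 bit, a characteristic keyword
template (fired with high probability on top of sparse background noise),
an acupoint template with per-bit flip noise, per-disease Gaussian basic
info, and a deterministic traditional-medicine diagnosis code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import benchmark
from .exceptions import ConfigurationError
from .records_io import ClinicalRecord, Dataset, DatasetSchema

__all__ = [
    "SyntheticConfig",
    "make_config",
    "default_config",
    "generate_records",
    "zero_noise",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of one synthetic dataset draw."""

    n_records: int
    schema: DatasetSchema
    n_diseases: int
    class_prior: tuple[float, ...]
    disease_to_icd10: tuple[int, ...]
    keyword_templates: tuple[tuple[int, ...], ...]
    acupoint_templates: tuple[tuple[int, ...], ...]
    tcm_dx_map: tuple[int, ...]
    basic_info_means: tuple[tuple[float, ...], ...]
    basic_info_sds: tuple[tuple[float, ...], ...]
    keyword_on_prob: float = 0.9
    keyword_bg_prob: float = 0.02
    acupoint_flip_prob: float = 0.05
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_records <= 0:
            raise ConfigurationError("n_records must be positive")
        if self.n_diseases <= 0:
            raise ConfigurationError("n_diseases must be positive")
        prior = np.asarray(self.class_prior, dtype=float)
        if prior.shape != (self.n_diseases,):
            raise ConfigurationError("class_prior length must equal n_diseases")
        if (prior < 0).any() or abs(prior.sum() - 1.0) > 1e-9:
            raise ConfigurationError("class_prior must be nonnegative and sum to 1")
        for p_name in ("keyword_on_prob", "keyword_bg_prob", "acupoint_flip_prob"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{p_name} must lie in [0, 1]")
        if len(self.disease_to_icd10) != self.n_diseases:
            raise ConfigurationError("disease_to_icd10 length must equal n_diseases")
        if len(set(self.disease_to_icd10)) != self.n_diseases:
            raise ConfigurationError("disease_to_icd10 must be injective")
        if max(self.disease_to_icd10) >= self.schema.n_icd10 or min(self.disease_to_icd10) < 0:
            raise ConfigurationError("disease_to_icd10 indexes outside the ICD-10 range")
        for c, tpl in enumerate(self.keyword_templates):
            if tpl and (max(tpl) >= self.schema.n_keywords or min(tpl) < 0):
                raise ConfigurationError(f"keyword template {c} indexes outside schema")
        for c, tpl in enumerate(self.acupoint_templates):
            if tpl and (max(tpl) >= self.schema.n_acupoints or min(tpl) < 0):
                raise ConfigurationError(f"acupoint template {c} indexes outside schema")
        for code in self.tcm_dx_map:
            if code not in self.schema.tcm_codes:
                raise ConfigurationError(f"tcm code {code} not declared in schema")
        means = np.asarray(self.basic_info_means, dtype=float)
        sds = np.asarray(self.basic_info_sds, dtype=float)
        want = (self.n_diseases, self.schema.n_basic)
        if means.shape != want or sds.shape != want:
            raise ConfigurationError("basic_info_means/sds must be (n_diseases, n_basic)")
        if (sds < 0).any():
            raise ConfigurationError("basic_info_sds must be nonnegative")
        return self


def make_config(
    n_records: int,
    n_diseases: int,
    *,
    n_icd10: int,
    n_keywords: int,
    n_acupoints: int,
    n_basic: int = 11,
    class_prior: np.ndarray | None = None,
    kw_per_disease: int = 8,
    acu_per_disease: int = 6,
    keyword_on_prob: float = 0.9,
    keyword_bg_prob: float = 0.02,
    acupoint_flip_prob: float = 0.05,
    shared_basic_info: bool = False,
    seed: int = 0,
) -> SyntheticConfig:
    """Assemble a config with deterministic per-disease templates.

    Keyword templates are disjoint index blocks (each disease has exclusive
    characteristic keywords); acupoint templates are drawn from a seeded
    stream and may overlap across diseases, like real treatment plans do.
    """
    if n_diseases > n_icd10:
        raise ConfigurationError("need at least one ICD-10 index per disease")
    kw_per = min(kw_per_disease, n_keywords // n_diseases)
    if kw_per < 1:
        raise ConfigurationError("too few keywords for one template entry per disease")
    rng = np.random.default_rng(seed)
    kw_templates = tuple(
        tuple(range(c * kw_per, (c + 1) * kw_per)) for c in range(n_diseases)
    )
    acu_per = min(acu_per_disease, n_acupoints)
    acu_templates = tuple(
        tuple(sorted(rng.choice(n_acupoints, size=acu_per, replace=False).tolist()))
        for _ in range(n_diseases)
    )
    prior = (
        np.full(n_diseases, 1.0 / n_diseases)
        if class_prior is None
        else np.asarray(class_prior, dtype=float)
    )
    if shared_basic_info:
        # one population for all diseases: basic info carries no class signal,
        # so (zero-noise) separability rests entirely on the keyword templates
        means = np.tile(rng.uniform(20.0, 70.0, size=(1, n_basic)), (n_diseases, 1))
        sds = np.tile(rng.uniform(0.5, 5.0, size=(1, n_basic)), (n_diseases, 1))
    else:
        means = rng.uniform(20.0, 70.0, size=(n_diseases, n_basic))
        sds = rng.uniform(0.5, 5.0, size=(n_diseases, n_basic))
    schema = DatasetSchema(
        n_icd10=n_icd10,
        n_basic=n_basic,
        n_keywords=n_keywords,
        n_acupoints=n_acupoints,
        tcm_codes=tuple(range(n_diseases)),
    )
    cfg = SyntheticConfig(
        n_records=n_records,
        schema=schema,
        n_diseases=n_diseases,
        class_prior=tuple(prior.tolist()),
        disease_to_icd10=tuple(range(n_diseases)),
        keyword_templates=kw_templates,
        acupoint_templates=acu_templates,
        tcm_dx_map=tuple(range(n_diseases)),
        basic_info_means=tuple(map(tuple, means.tolist())),
        basic_info_sds=tuple(map(tuple, sds.tolist())),
        keyword_on_prob=keyword_on_prob,
        keyword_bg_prob=keyword_bg_prob,
        acupoint_flip_prob=acupoint_flip_prob,
        seed=seed,
    )
    return cfg.validate()


def default_config(scale: str, seed: int = 0) -> SyntheticConfig:
    """Canonical configs: ``"paper"`` mirrors the published schema and class
    sizes (2835 records, 21 diseases, 31 ICD-10 labels, 4000 keywords, 53
    acupoints); ``"small"`` is a fast test-sized config."""
    if scale == "paper":
        sizes = np.asarray(benchmark.DISEASE_SIZES, dtype=float)
        return make_config(
            n_records=int(sizes.sum()),
            n_diseases=21,
            n_icd10=31,
            n_keywords=4000,
            n_acupoints=53,
            class_prior=sizes / sizes.sum(),
            seed=seed,
        )
    if scale == "small":
        return make_config(
            n_records=240,
            n_diseases=6,
            n_icd10=10,
            n_keywords=40,
            n_acupoints=12,
            kw_per_disease=6,
            acu_per_disease=4,
            shared_basic_info=True,
            seed=seed,
        )
    raise ConfigurationError(f"unknown scale {scale!r} (expected 'small' or 'paper')")


def generate_records(cfg: SyntheticConfig) -> Dataset:
    """Draw one dataset from ``cfg``; identical configs give identical data."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, C = cfg.n_records, cfg.n_diseases
    K, A = cfg.schema.n_keywords, cfg.schema.n_acupoints

    disease = rng.choice(C, size=n, p=np.asarray(cfg.class_prior))

    kw_template = np.zeros((C, K), dtype=bool)
    for c, tpl in enumerate(cfg.keyword_templates):
        kw_template[c, list(tpl)] = True
    acu_template = np.zeros((C, A), dtype=bool)
    for c, tpl in enumerate(cfg.acupoint_templates):
        acu_template[c, list(tpl)] = True

    tpl_kw = kw_template[disease]
    fires = rng.random((n, K)) < cfg.keyword_on_prob
    background = rng.random((n, K)) < cfg.keyword_bg_prob
    keywords = np.where(tpl_kw, fires, background).astype(np.uint8)

    flips = rng.random((n, A)) < cfg.acupoint_flip_prob
    acupoints = (acu_template[disease] ^ flips).astype(np.uint8)

    means = np.asarray(cfg.basic_info_means)[disease]
    sds = np.asarray(cfg.basic_info_sds)[disease]
    basic = rng.normal(means, sds)

    icd10_idx = np.asarray(cfg.disease_to_icd10)[disease]
    tcm = np.asarray(cfg.tcm_dx_map)[disease]

    records = []
    for i in range(n):
        icd10 = np.zeros(cfg.schema.n_icd10, dtype=np.uint8)
        icd10[icd10_idx[i]] = 1
        records.append(
            ClinicalRecord(
                icd10=icd10,
                basic_info=basic[i],
                text_features=keywords[i],
                acupoints=acupoints[i],
                tcm_dx=int(tcm[i]),
            )
        )
    return Dataset(records, cfg.schema)


def zero_noise(cfg: SyntheticConfig, seed: int | None = None) -> SyntheticConfig:
    """A copy of ``cfg`` with all noise switched off (templates reproduced exactly)."""
    out = replace(
        cfg,
        keyword_on_prob=1.0,
        keyword_bg_prob=0.0,
        acupoint_flip_prob=0.0,
    )
    if seed is not None:
        out = replace(out, seed=seed)
    return out
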