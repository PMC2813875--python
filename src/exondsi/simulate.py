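"""Synthetic exon-array data with planted expression and splicing structure.

The generator emulates a 13-group design: one whole-blood group (4 samples),
one CD34+ hematopoietic stem/progenitor (HSPC) group (3 samples) and 11
solid tissues (3 samples each), on the log2 scale of probeset summaries.

Structure planted per gene:

* a per-gene baseline and per-probeset affinity offset (constant across
  samples, so it cancels in group differences);
* optional whole-gene differential expression in one or both hematopoietic
  groups (direction and magnitude recorded in the truth table);
* optional localized alternative-splicing (AS) events — cassette exon,
  intron retention, alternative first/last exon, exon extension — that move
  a contiguous probeset span in exactly one hematopoietic group;
* additive Gaussian noise on the log2 scale (log-normal multiplicative on
  the raw scale);
* a fraction of probesets at the background noise floor, whose detection
  p-values are uniform-like and hence mostly non-significant.

Detection p-values are produced analytically from a one-sided Gaussian tail
of signal above the noise floor — the pipeline needs a filterable p-value,
not a probe-level background model.

Everything is deterministic given ``SimConfig.seed``; the returned
:class:`TruthTable` makes planted structure exactly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ProbesetAnnotation, ProbesetMatrix, SampleGroups

__all__ = [
    "SimConfig",
    "AsEvent",
    "DeGene",
    "TruthTable",
    "EVENT_TYPES",
    "SOLID_TISSUES",
    "simulate_dataset",
    "plant_as_event",
    "simulate_dabg",
    "simulate_categories",
]

EVENT_TYPES = (
    "cassette",
    "intron_retention",
    "alt_first",
    "alt_last",
    "exon_extension",
)

#: The 11 solid tissues of the reference compendium; spleen carries a mixed
#: hematopoietic/non-hematopoietic content and is excluded from comparison
#: plans downstream.
SOLID_TISSUES = (
    "breast",
    "cerebellum",
    "heart",
    "kidney",
    "liver",
    "muscle",
    "pancreas",
    "prostate",
    "spleen",
    "testis",
    "thyroid",
)

HEMATO_GROUPS = ("blood", "cd34")


class ConfigurationError(ValueError):
    """SimConfig violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset.

    Defaults mirror the study design: 13 groups (blood, CD34+ HSPC and the
    11-tissue solid compendium), 3 samples per group and 4 for blood.  All
    signal quantities are in log2 units.
    """

    n_genes: int = 300
    probesets_min: int = 4
    probesets_max: int = 8
    baseline_log2: float = 8.0
    noise_sd: float = 0.3
    de_fraction: float = 0.1
    de_effect_log2: float = 2.0
    as_fraction: float = 0.1
    as_effect_log2: float = 2.0
    background_fraction: float = 0.1
    seed: int = 0
    samples_per_group: int = 3
    blood_samples: int = 4
    groups: tuple[str, ...] = HEMATO_GROUPS + SOLID_TISSUES

    def __post_init__(self) -> None:
        if self.probesets_min < 4:
            raise ConfigurationError(
                "probesets_min must be >= 4: dsi scoring needs a window of "
                "four contiguous probesets"
            )
        if self.probesets_max < self.probesets_min:
            raise ConfigurationError("probesets_max < probesets_min")
        for name in ("de_fraction", "as_fraction", "background_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.n_genes < 1 or self.samples_per_group < 2:
            raise ConfigurationError("need n_genes >= 1 and samples_per_group >= 2")

    @property
    def noise_floor(self) -> float:
        """Background signal level, 4 log2 units under the expressed baseline."""
        return self.baseline_log2 - 4.0

    def group_sizes(self) -> dict[str, int]:
        return {
            g: (self.blood_samples if g == "blood" else self.samples_per_group)
            for g in self.groups
        }


@dataclass(frozen=True)
class AsEvent:
    """One planted alternative-splicing event."""

    gene: str
    event_type: str
    span: tuple[int, int]  # inclusive ordinal range of affected probesets
    group: str  # the group whose profile is shifted
    magnitude: float  # log2 shift applied inside the span


@dataclass(frozen=True)
class DeGene:
    """One planted whole-gene differential-expression effect."""

    gene: str
    direction: int  # +1 up, -1 down in the affected groups
    groups: tuple[str, ...]  # affected hematopoietic group(s)
    magnitude: float


@dataclass
class TruthTable:
    """Ground truth of planted structure, exactly recoverable."""

    de_genes: list[DeGene] = field(default_factory=list)
    as_events: list[AsEvent] = field(default_factory=list)

    @property
    def de_gene_ids(self) -> set[str]:
        return {g.gene for g in self.de_genes}

    @property
    def as_gene_ids(self) -> set[str]:
        return {e.gene for e in self.as_events}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "kind": "de",
                "gene": g.gene,
                "detail": "up" if g.direction > 0 else "down",
                "span": "",
                "groups": "+".join(g.groups),
                "magnitude": g.direction * g.magnitude,
            }
            for g in self.de_genes
        ] + [
            {
                "kind": "as",
                "gene": e.gene,
                "detail": e.event_type,
                "span": f"{e.span[0]}-{e.span[1]}",
                "groups": e.group,
                "magnitude": e.magnitude,
            }
            for e in self.as_events
        ]
        return pd.DataFrame(
            rows, columns=["kind", "gene", "detail", "span", "groups", "magnitude"]
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def plant_as_event(
    profile: pd.DataFrame, event_type: str, span: tuple[int, int], group: str,
    magnitude: float,
) -> pd.DataFrame:
    """Apply one AS event to a per-group mean profile.

    ``profile`` is probeset-position x group (log2 means).  For cassette and
    intron-retention events the probesets inside ``span`` shift; for
    alternative first/last exons and exon extensions the span is one side of
    a breakpoint, which the caller encodes directly in ``span``.  Only the
    named group changes; ``magnitude == 0`` is the identity.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    lo, hi = span
    n = len(profile)
    if not (0 <= lo <= hi < n):
        raise IndexError(f"span {span} outside gene of {n} probesets")
    out = profile.copy()
    out.iloc[lo : hi + 1, out.columns.get_loc(group)] += magnitude
    return out


def simulate_dabg(
    signals: pd.DataFrame, noise_floor: float, scale: float = 1.0
) -> pd.DataFrame:
    """Analytic detection p-values: upper Gaussian tail of signal above floor.

    p = P(Z >= (signal - floor)/scale).  At the floor p = 0.5; an expressed
    probeset 2+ log2 units above the floor receives p <= ~0.05 (scale 1);
    a background probeset whose signal is floor + N(0, scale) noise receives
    an exactly Uniform(0,1) p-value.
    """
    z = (signals.to_numpy() - noise_floor) / scale
    p = stats.norm.sf(z)
    # DABG p-values live in (0, 1]; clip away exact zeros from extreme tails
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return pd.DataFrame(p, index=signals.index, columns=signals.columns)


def _sample_ids(config: SimConfig) -> tuple[list[str], dict[str, str]]:
    ids, assignment = [], {}
    for g, size in config.group_sizes().items():
        for i in range(1, size + 1):
            sid = f"{g}_{i}"
            ids.append(sid)
            assignment[sid] = g
    return ids, assignment


def _choose_span(rng: np.random.Generator, event_type: str, n_ps: int) -> tuple[int, int]:
    """Pick the affected ordinal span for an event type within a gene."""
    if event_type in ("cassette", "intron_retention"):
        width = int(rng.integers(1, 3))  # 1-2 probesets
        lo = int(rng.integers(1, n_ps - width))  # keep flanks on both sides
        return lo, lo + width - 1
    if event_type == "alt_first":
        bp = int(rng.integers(1, n_ps - 1))
        return 0, bp - 1
    if event_type == "alt_last":
        bp = int(rng.integers(1, n_ps - 1))
        return bp, n_ps - 1
    # exon_extension: a single probeset adjacent to an expressed exon
    pos = int(rng.integers(1, n_ps - 1))
    return pos, pos


def simulate_dataset(
    config: SimConfig,
) -> tuple[ProbesetMatrix, ProbesetAnnotation, SampleGroups, TruthTable]:
    """Generate one dataset with known DE and AS structure.

    Returns the signal matrix (with detection p-values attached), the
    probeset annotation, the sample-group table and the truth table.
    Identical config (including seed) gives byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    sample_ids, assignment = _sample_ids(config)
    groups = SampleGroups(assignment)
    group_names = list(config.groups)

    gene_ids = [f"TC{i:05d}" for i in range(config.n_genes)]
    n_ps_per_gene = rng.integers(
        config.probesets_min, config.probesets_max + 1, size=config.n_genes
    )

    # deterministic planted-structure assignment: shuffle gene ids, take first k
    n_de = round(config.de_fraction * config.n_genes)
    n_as = round(config.as_fraction * config.n_genes)
    order = rng.permutation(config.n_genes)
    de_idx = set(order[:n_de].tolist())
    as_idx = set(order[n_de : n_de + n_as].tolist())

    truth = TruthTable()
    profiles: list[pd.DataFrame] = []
    ann_rows: list[dict] = []
    background_ps: list[str] = []
    ps_counter = 0

    for gi, (gene, n_ps) in enumerate(zip(gene_ids, n_ps_per_gene)):
        baseline = config.baseline_log2 + rng.normal(0.0, 1.0)
        affinity = rng.normal(0.0, 0.5, size=n_ps)
        profile = pd.DataFrame(
            np.add.outer(affinity, np.zeros(len(group_names))) + baseline,
            columns=group_names,
        )

        if gi in de_idx:
            direction = 1 if rng.random() < 0.5 else -1
            # affected set: blood only, CD34 only, or both hematopoietic groups
            affected = (("blood",), ("cd34",), HEMATO_GROUPS)[int(rng.integers(0, 3))]
            for g in affected:
                profile[g] += direction * config.de_effect_log2
            truth.de_genes.append(
                DeGene(gene, direction, tuple(affected), config.de_effect_log2)
            )

        if gi in as_idx:
            event_type = EVENT_TYPES[len(truth.as_events) % len(EVENT_TYPES)]
            span = _choose_span(rng, event_type, n_ps)
            group = HEMATO_GROUPS[int(rng.integers(0, 2))]
            magnitude = config.as_effect_log2 * (1 if rng.random() < 0.5 else -1)
            profile = plant_as_event(profile, event_type, span, group, magnitude)
            truth.as_events.append(AsEvent(gene, event_type, span, group, magnitude))

        for j in range(n_ps):
            ps_id = f"PS{ps_counter:07d}"
            ps_counter += 1
            ann_rows.append(
                {
                    "probeset_id": ps_id,
                    "transcript_cluster_id": gene,
                    "ordinal": j,
                    "evidence": "core" if rng.random() < 0.7 else "full",
                }
            )
            # background probesets only in structurally unplanted genes, so
            # truth stays exactly recoverable after DABG filtering
            if (
                gi not in as_idx
                and gi not in de_idx
                and rng.random() < config.background_fraction
            ):
                background_ps.append(ps_id)
        profiles.append(profile)

    annotation = ProbesetAnnotation(
        pd.DataFrame(ann_rows).set_index("probeset_id")
    )
    all_ps = annotation.probeset_ids

    # expand group means to per-sample values and add replicate noise
    mean_matrix = np.vstack([p.to_numpy() for p in profiles])  # ps x groups
    col_of_group = {g: k for k, g in enumerate(group_names)}
    sample_cols = np.array([col_of_group[assignment[s]] for s in sample_ids])
    signals = mean_matrix[:, sample_cols]

    bg_mask = np.isin(np.array(all_ps), np.array(background_ps, dtype=object))
    signals = signals.copy()
    signals[bg_mask, :] = config.noise_floor
    signals += rng.normal(0.0, config.noise_sd, size=signals.shape)

    sig_df = pd.DataFrame(signals, index=all_ps, columns=sample_ids)
    detection = simulate_dabg(sig_df, config.noise_floor, scale=config.noise_sd)
    matrix = ProbesetMatrix(sig_df, detection)
    return matrix, annotation, groups, truth


def simulate_categories(
    gene_ids: list[str],
    truth: TruthTable,
    n_categories: int = 20,
    category_size: int = 30,
    seed: int = 0,
    as_enrichment: float = 0.5,
) -> dict[str, set[str]]:
    """Synthetic functional-category map for exercising enrichment.

    Produces ``n_categories`` random categories plus one category
    (``motility_like``) deliberately enriched in planted AS genes — a stand-in
    for a real gene-ontology release, which is user-supplied in real analyses.
    """
    rng = np.random.default_rng(seed)
    genes = np.array(gene_ids)
    cats: dict[str, set[str]] = {}
    for i in range(n_categories):
        size = min(category_size, len(genes))
        cats[f"CAT{i:03d}"] = set(rng.choice(genes, size=size, replace=False))
    as_genes = sorted(truth.as_gene_ids & set(gene_ids))
    n_from_as = round(as_enrichment * min(category_size, len(genes)))
    n_from_as = min(n_from_as, len(as_genes))
    rest_pool = np.array(sorted(set(gene_ids) - set(as_genes)))
    n_rest = min(category_size - n_from_as, len(rest_pool))
    enriched = set(rng.choice(np.array(as_genes), size=n_from_as, replace=False)) | set(
        rng.choice(rest_pool, size=n_rest, replace=False)
    )
    cats["motility_like"] = enriched
    return cats
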