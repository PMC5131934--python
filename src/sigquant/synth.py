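"""Synthetic signature cohorts for end-to-end testing without real data.

The generator emulates the statistical structure the method assumes in an
MCYT-style corpus: per subject, an ensemble of genuine signatures (small
reproduction jitter around a personal template) and skilled forgeries
(larger parameter scatter, a smooth time warp from the slower, deliberate
reproduction, and physiological hand tremor).  Subjects fall into three
planted stroke-complexity classes (low / medium / high), which drive the
ordinal entropy of their trajectories and hence the recoverable typology.

A subject template is a sum of K stroke components: Gaussian-envelope
damped oscillations in x and y riding on a left-to-right drift,

    x(t) = d_x t + sum_k A_k exp(-((t - t_k)/w_k)^2) sin(2 pi f_k (t - t_k) + phi_k)

with the per-class total cycle budget controlling how many direction
changes (hence how rich an ordinal spectrum) the signature has.  This is
a statistical stand-in, not a biomechanical handwriting model.

Determinism: each subject draws from its own substream of the master
seed, so a cohort's first k subjects are identical regardless of
``n_subjects``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import MANIFEST_COLUMNS, RawSignature, write_manifest, write_signature

DEFAULT_SEED = 20161201

COMPLEXITY_CLASSES = ("low", "medium", "high")

__all__ = [
    "DEFAULT_SEED",
    "COMPLEXITY_CLASSES",
    "GeneratorConfig",
    "SubjectTemplate",
    "SyntheticCohort",
    "simulate_subject",
    "realize_signature",
    "simulate_cohort",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator parameters.

    Defaults mirror the MCYT-100 protocol shape: 100 subjects, 25 genuine
    + 25 skilled forgeries each, raw sample counts varying in the range a
    100 Hz tablet produces for 3-15 s signatures.  Jitters are relative
    (fractional) perturbation scales of the template parameters; tremor
    amplitude is in template coordinate units (signatures span ~1 unit).
    """

    n_subjects: int = 100
    n_genuine: int = 25
    n_forgery: int = 25
    samples_range: tuple[int, int] = (300, 1500)
    complexity_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    stroke_ranges: dict = field(
        default_factory=lambda: {"low": (2, 4), "medium": (6, 9), "high": (12, 18)}
    )
    cycle_ranges: dict = field(
        default_factory=lambda: {"low": (4, 9), "medium": (16, 28), "high": (40, 60)}
    )
    genuine_jitter: float = 0.03
    forgery_jitter: float = 0.12
    noise_sd: float = 0.0001
    tremor_amplitude: float = 0.025
    tremor_cycles: tuple[float, float] = (60.0, 100.0)
    warp_strength: float = 0.03
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.genuine_jitter < 0 or self.forgery_jitter <= self.genuine_jitter:
            raise ValueError("need 0 <= genuine_jitter < forgery_jitter")
        if abs(sum(self.complexity_mix) - 1.0) > 1e-9:
            raise ValueError("complexity_mix proportions must sum to 1")
        if self.n_genuine < 1 or self.n_forgery < 1 or self.n_subjects < 1:
            raise ValueError("counts must be positive")
        if self.samples_range[0] < 5 or self.samples_range[1] < self.samples_range[0]:
            raise ValueError("invalid samples_range")


@dataclass
class SubjectTemplate:
    """Frozen per-subject stroke parameters; evaluate() renders the path."""

    subject_id: str
    complexity_class: str
    centers: np.ndarray  # stroke centers t_k in (0, 1)
    widths: np.ndarray  # envelope widths w_k
    freqs: np.ndarray  # oscillation frequencies f_k (cycles per unit time)
    amp_x: np.ndarray
    amp_y: np.ndarray
    phase_x: np.ndarray
    phase_y: np.ndarray
    drift_x: float
    drift_y: float

    @property
    def n_strokes(self) -> int:
        return len(self.centers)

    def evaluate(
        self,
        t: np.ndarray,
        amp_scale_x: np.ndarray | None = None,
        amp_scale_y: np.ndarray | None = None,
        freq_scale: np.ndarray | None = None,
        phase_shift_x: np.ndarray | None = None,
        phase_shift_y: np.ndarray | None = None,
        drift_scale: tuple[float, float] = (1.0, 1.0),
    ) -> tuple[np.ndarray, np.ndarray]:
        """Render the stroke sum at times ``t`` with optional per-stroke scalings."""
        k = self.n_strokes
        ones = np.ones(k)
        asx = ones if amp_scale_x is None else amp_scale_x
        asy = ones if amp_scale_y is None else amp_scale_y
        fs = ones if freq_scale is None else freq_scale
        psx = np.zeros(k) if phase_shift_x is None else phase_shift_x
        psy = np.zeros(k) if phase_shift_y is None else phase_shift_y
        dt = t[:, None] - self.centers[None, :]
        env = np.exp(-((dt / self.widths[None, :]) ** 2))
        arg = 2.0 * np.pi * (self.freqs * fs)[None, :] * dt
        x = drift_scale[0] * self.drift_x * t + np.sum(
            (self.amp_x * asx)[None, :] * env * np.sin(arg + (self.phase_x + psx)[None, :]),
            axis=1,
        )
        y = drift_scale[1] * self.drift_y * t + np.sum(
            (self.amp_y * asy)[None, :] * env * np.sin(arg + (self.phase_y + psy)[None, :]),
            axis=1,
        )
        return x, y


def simulate_subject(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    complexity_class: str,
    subject_id: str = "",
) -> SubjectTemplate:
    """Draw one subject template from its complexity class."""
    if complexity_class not in COMPLEXITY_CLASSES:
        raise ValueError(f"unknown complexity class {complexity_class!r}")
    k_lo, k_hi = cfg.stroke_ranges[complexity_class]
    k = int(rng.integers(k_lo, k_hi + 1))
    centers = (np.arange(k) + 0.5) / k + rng.uniform(-0.1 / k, 0.1 / k, size=k)
    widths = (0.6 / k) * rng.uniform(0.8, 1.3, size=k)
    c_lo, c_hi = cfg.cycle_ranges[complexity_class]
    total_cycles = rng.uniform(c_lo, c_hi)
    per_stroke = (total_cycles / k) * rng.uniform(0.7, 1.3, size=k)
    # cycles within a stroke live mostly inside the +-w envelope (width 2w)
    freqs = per_stroke / (2.0 * widths)
    sign_x = rng.choice([-1.0, 1.0], size=k)
    sign_y = rng.choice([-1.0, 1.0], size=k)
    return SubjectTemplate(
        subject_id=subject_id,
        complexity_class=complexity_class,
        centers=centers,
        widths=widths,
        freqs=freqs,
        amp_x=sign_x * rng.uniform(0.2, 1.0, size=k),
        amp_y=sign_y * rng.uniform(0.2, 1.0, size=k),
        phase_x=rng.uniform(0, 2 * np.pi, size=k),
        phase_y=rng.uniform(0, 2 * np.pi, size=k),
        drift_x=rng.uniform(0.8, 1.6),
        drift_y=rng.uniform(-0.3, 0.3),
    )


def _monotone_warp(t: np.ndarray, rng: np.random.Generator, strength: float) -> np.ndarray:
    """Smooth random time warp fixing 0 and 1; amplitude kept below the
    monotonicity bound |w'| < 1."""
    m = rng.uniform(1.0, 3.0)
    amp = strength * rng.uniform(0.5, 1.0)
    psi = rng.uniform(0, 2 * np.pi)
    warped = t + amp * np.sin(np.pi * t) * np.sin(2 * np.pi * m * t + psi)
    return np.clip(warped, 0.0, 1.0)


def realize_signature(
    template: SubjectTemplate,
    authenticity: str,
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    signature_id: str = "",
) -> RawSignature:
    """Render one genuine or forged realization of a subject template.

    Genuine: template parameters jittered at ``genuine_jitter`` plus
    observation noise.  Forgery: jitter at ``forgery_jitter``, a smooth
    monotone time warp (deliberate reproduction), and additive hand
    tremor, which raises the ordinal entropy of the rendered path.
    """
    if authenticity not in ("genuine", "forgery"):
        raise ValueError("authenticity must be 'genuine' or 'forgery'")
    jitter = cfg.genuine_jitter if authenticity == "genuine" else cfg.forgery_jitter
    k = template.n_strokes
    n = int(rng.integers(cfg.samples_range[0], cfg.samples_range[1] + 1))
    t = np.linspace(0.0, 1.0, n)
    if authenticity == "forgery":
        t_eval = _monotone_warp(t, rng, cfg.warp_strength)
    else:
        t_eval = t
    x, y = template.evaluate(
        t_eval,
        amp_scale_x=1.0 + jitter * rng.standard_normal(k),
        amp_scale_y=1.0 + jitter * rng.standard_normal(k),
        freq_scale=1.0 + jitter * rng.standard_normal(k),
        phase_shift_x=jitter * np.pi * rng.standard_normal(k),
        phase_shift_y=jitter * np.pi * rng.standard_normal(k),
        drift_scale=(1.0 + jitter * rng.standard_normal(), 1.0 + jitter * rng.standard_normal()),
    )
    if authenticity == "forgery" and cfg.tremor_amplitude > 0:
        for coord in (x, y):
            c = rng.uniform(*cfg.tremor_cycles)
            amp = cfg.tremor_amplitude * rng.uniform(0.7, 1.3)
            coord += amp * np.sin(2 * np.pi * c * t + rng.uniform(0, 2 * np.pi))
    if cfg.noise_sd > 0:
        x = x + cfg.noise_sd * rng.standard_normal(n)
        y = y + cfg.noise_sd * rng.standard_normal(n)
    return RawSignature(
        x=x,
        y=y,
        subject_id=template.subject_id,
        signature_id=signature_id,
        authenticity=authenticity,
    )


@dataclass
class SyntheticCohort:
    """In-memory cohort: signatures plus the planted class of each subject."""

    signatures: list[RawSignature]
    complexity_classes: dict[str, str]
    config: GeneratorConfig

    def subject_ids(self) -> list[str]:
        return sorted(self.complexity_classes)


def _subject_class(rng: np.random.Generator, mix: tuple[float, float, float]) -> str:
    return str(rng.choice(COMPLEXITY_CLASSES, p=np.asarray(mix) / np.sum(mix)))


def simulate_cohort(cfg: GeneratorConfig | None = None, out_dir=None) -> SyntheticCohort:
    """Generate a full cohort; optionally write it to disk.

    When ``out_dir`` is given, each signature is written in the columns
    dialect, together with ``manifest.csv`` and the resolved generator
    config as ``generator.yaml``.
    """
    cfg = cfg or GeneratorConfig()
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_subjects)
    signatures: list[RawSignature] = []
    classes: dict[str, str] = {}
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        subject_id = f"s{i + 1:03d}"
        cls = _subject_class(rng, cfg.complexity_mix)
        classes[subject_id] = cls
        template = simulate_subject(rng, cfg, cls, subject_id=subject_id)
        for j in range(cfg.n_genuine):
            signatures.append(
                realize_signature(template, "genuine", rng, cfg, signature_id=f"g{j + 1:02d}")
            )
        for j in range(cfg.n_forgery):
            signatures.append(
                realize_signature(template, "forgery", rng, cfg, signature_id=f"f{j + 1:02d}")
            )
    cohort = SyntheticCohort(signatures=signatures, complexity_classes=classes, config=cfg)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: SyntheticCohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sig in cohort.signatures:
        fname = f"{sig.subject_id}_{sig.signature_id}.txt"
        try:
            write_signature(out_dir / fname, sig)
        except OSError as exc:
            raise OSError(f"failed writing signature file {out_dir / fname}: {exc}") from exc
        rows.append(
            {
                "path": fname,
                "subject_id": sig.subject_id,
                "signature_id": sig.signature_id,
                "authenticity": sig.authenticity,
            }
        )
    write_manifest(out_dir / "manifest.csv", pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)))
    meta = asdict(cohort.config)
    meta["complexity_classes"] = dict(sorted(cohort.complexity_classes.items()))
    with open(out_dir / "generator.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
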