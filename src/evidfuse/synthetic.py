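"""Synthetic multimodal ICU cohorts and the EHR preprocessing rules.

The generator emulates the statistical shape of a multimodal ICU EHR
extract: a structured table mixing numeric vitals/labs, binary
treatments/comorbidities and a categorical admission type (tagged by
source), free-text notes of up to four types whose token content
carries class signal, ~12% positive prevalence, and MCAR missingness.
A per-patient severity latent shared between the modalities (weighted
by ``modality_correlation``) controls how complementary vs redundant
the two modality signals are.

Preprocessing implements the pipeline's contractual rules: drop
features with ≥50% missingness, one-hot encode categoricals, z-score
numerics, impute median/mode — all fitted on the training split only —
plus four numeric imputation strategies (mean, median, KNN, iterative),
note prefixing/newline concatenation, and fixed 512-token sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import json

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer, KNNImputer, SimpleImputer

from .encoders import PAD_TOKEN

__all__ = [
    "NOTE_TYPES",
    "CohortSpec",
    "RawCohort",
    "generate",
    "StructuredPreprocessor",
    "preprocess_structured",
    "impute",
    "format_patient_notes",
    "tokenize",
    "preprocess_notes",
    "label_plos",
    "write_cohort",
    "read_cohort",
    "separable_spec",
    "noise_text_spec",
    "noise_struct_spec",
]

NOTE_TYPES = ("Nursing", "Nursing/Other", "Physician", "Radiology")

SOURCES = ("demographics", "vitals_labs", "treatments", "comorbidities")


@dataclass
class CohortSpec:
    """Generator settings; the defaults are the study conditions used by
    the package's synthetic benchmark (complementary-signal regime)."""

    n_patients: int = 5000
    positive_rate: float = 0.12
    n_numeric: int = 18           # vitals/labs columns
    numeric_informative: int = 6
    numeric_effect: float = 0.5   # class-conditional mean shift, in SD units
    n_binary: int = 12            # treatments + comorbidities
    binary_informative: int = 4
    binary_effect: float = 0.18   # class-conditional rate shift
    missing_rate: float = 0.08    # MCAR cell rate on numeric/categorical cols
    vocab_size: int = 200
    note_length: int = 40         # background tokens per note
    text_informative_tokens: int = 12
    text_effect: float = 1.5      # class shift on the token-presence logit
    text_base_logit: float = -2.0
    modality_correlation: float = 0.3  # weight of the shared severity latent
    note_types: tuple = NOTE_TYPES
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        for name in ("positive_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.numeric_informative > self.n_numeric:
            raise ValueError("more informative numeric features than features")
        if self.numeric_effect != 0.0 and self.numeric_informative == 0:
            raise ValueError("numeric effect requested with zero informative features")
        if self.text_effect != 0.0 and self.text_informative_tokens == 0:
            raise ValueError("text effect requested with zero informative tokens")


@dataclass
class RawCohort:
    structured: pd.DataFrame           # indexed by patient id; NaN = missing
    tags: dict                         # column -> {"source": ..., "type": ...}
    notes: list                        # records {patient_id, note_type, text}
    labels: np.ndarray                 # one binary label per patient
    ids: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.labels) != len(self.structured):
            raise ValueError("one label per patient required")
        known = set(self.structured.index)
        for rec in self.notes:
            if rec["patient_id"] not in known:
                raise ValueError(f"note for unknown patient {rec['patient_id']!r}")


def separable_spec(seed: int = 0) -> CohortSpec:
    """Strong independent signal in both modalities: the combined signal
    is (nearly) separable."""
    return CohortSpec(
        numeric_effect=1.1, text_effect=3.5,
        modality_correlation=0.0, missing_rate=0.0, seed=seed,
    )


def noise_text_spec(seed: int = 0) -> CohortSpec:
    """Structured signal as in the default regime; notes carry no class
    signal at all."""
    return CohortSpec(text_effect=0.0, modality_correlation=0.0, seed=seed)


def noise_struct_spec(seed: int = 0) -> CohortSpec:
    """Text signal as in the default regime; structured features are
    pure noise."""
    return CohortSpec(
        numeric_effect=0.0, binary_effect=0.0,
        modality_correlation=0.0, seed=seed,
    )


def generate(spec: CohortSpec) -> RawCohort:
    """Draw a cohort: Bernoulli labels, class-conditional Gaussian
    numerics, class-conditional Bernoulli binaries, token-based notes,
    and MCAR missingness.  Fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    ids = [f"p{i:05d}" for i in range(n)]
    y = (rng.random(n) < spec.positive_rate).astype(int)
    severity = rng.standard_normal(n)  # shared latent, class-independent
    rho = spec.modality_correlation

    cols: dict[str, np.ndarray] = {}
    tags: dict[str, dict] = {}

    # demographics: age mildly informative, weight noise, admission type
    # skewed; the demographic signal scales with the effect parameters so
    # zero-effect specs carry no class signal anywhere
    cols["age"] = 62.0 + 8.0 * spec.numeric_effect * y + 15.0 * rng.standard_normal(n)
    tags["age"] = {"source": "demographics", "type": "numerical"}
    cols["weight"] = 82.0 + 23.0 * rng.standard_normal(n)
    tags["weight"] = {"source": "demographics", "type": "numerical"}
    p_emerg = np.clip(0.78 + 0.78 * spec.binary_effect * y, 0, 1)
    u = rng.random(n)
    adm = np.where(u < p_emerg, "emergency",
                   np.where(u < p_emerg + 0.8 * (1 - p_emerg), "elective", "urgent"))
    cols["admission_type"] = adm
    tags["admission_type"] = {"source": "demographics", "type": "categorical"}

    # vitals / labs
    for j in range(spec.n_numeric):
        name = f"lab{j:02d}"
        x = rng.standard_normal(n)
        if j < spec.numeric_informative:
            x = x + spec.numeric_effect * y + rho * severity
        cols[name] = x
        tags[name] = {"source": "vitals_labs", "type": "numerical"}

    # treatments / comorbidities (binary)
    n_treat = spec.n_binary // 2
    for j in range(spec.n_binary):
        source = "treatments" if j < n_treat else "comorbidities"
        name = f"{'rx' if j < n_treat else 'cm'}{j:02d}"
        base = 0.15 + 0.2 * rng.random()
        p = np.clip(base + (spec.binary_effect * y if j < spec.binary_informative else 0.0), 0, 1)
        cols[name] = (rng.random(n) < p).astype(float)
        tags[name] = {"source": source, "type": "categorical"}

    df = pd.DataFrame(cols, index=pd.Index(ids, name="patient_id"))

    # MCAR missingness on numeric and categorical (non-binary) columns
    if spec.missing_rate > 0:
        for c in df.columns:
            if tags[c]["type"] == "numerical" or c == "admission_type":
                mask = rng.random(n) < spec.missing_rate
                if tags[c]["type"] == "numerical":
                    df.loc[mask, c] = np.nan
                else:
                    df[c] = df[c].where(~mask, np.nan)

    # notes: background tokens plus class-informative tokens whose
    # presence probability follows a logistic model in y and severity
    vocab = np.array([f"t{i:03d}" for i in range(spec.vocab_size)])
    info_tokens = np.array([f"sx{i:02d}" for i in range(spec.text_informative_tokens)])
    notes: list[dict] = []
    for i, pid in enumerate(ids):
        logit = spec.text_base_logit + spec.text_effect * y[i] + rho * severity[i]
        p_tok = 1.0 / (1.0 + np.exp(-logit))
        for note_type in spec.note_types:
            toks = list(rng.choice(vocab, size=spec.note_length))
            present = info_tokens[rng.random(len(info_tokens)) < p_tok]
            toks.extend(present)
            rng.shuffle(toks)
            notes.append({
                "patient_id": pid,
                "note_type": note_type,
                "text": " ".join(toks),
            })

    return RawCohort(structured=df, tags=tags, notes=notes, labels=y, ids=ids)


# -- structured preprocessing -------------------------------------------

class StructuredPreprocessor:
    """Fit on the training split only; transform any split.

    Rules: drop features with >=50% training missingness; impute median
    (numeric) / mode (categorical); z-score numerics with training
    mean/SD; one-hot encode categoricals over training categories
    (binary-valued columns stay a single 0/1 indicator).
    """

    def __init__(self, tags: dict, missing_threshold: float = 0.5):
        self.tags = tags
        self.missing_threshold = missing_threshold
        self.fitted = False

    def fit(self, train_df: pd.DataFrame) -> "StructuredPreprocessor":
        self.kept: list[str] = [
            c for c in train_df.columns
            if train_df[c].isna().mean() < self.missing_threshold
        ]
        self.stats: dict[str, dict] = {}
        for c in self.kept:
            col = train_df[c]
            if self.tags[c]["type"] == "numerical":
                med = float(col.median())
                filled = col.fillna(med)
                sd = float(filled.std(ddof=0))
                self.stats[c] = {
                    "median": med,
                    "mean": float(filled.mean()),
                    "sd": sd if sd > 1e-12 else 1.0,
                }
            else:
                counts = col.dropna().value_counts()
                if counts.empty:
                    raise ValueError(f"categorical column {c!r} has no observed values")
                self.stats[c] = {
                    "mode": counts.index[0],
                    "categories": sorted(counts.index.tolist(), key=str),
                }
        self.fitted = True
        return self

    def transform(self, df: pd.DataFrame):
        if not self.fitted:
            raise RuntimeError("fit() the preprocessor on the training split first")
        out_cols: list[np.ndarray] = []
        names: list[str] = []
        out_tags: list[dict] = []
        for c in self.kept:
            st = self.stats[c]
            tag = self.tags[c]
            if tag["type"] == "numerical":
                v = df[c].fillna(st["median"]).to_numpy(dtype=np.float64)
                out_cols.append((v - st["mean"]) / st["sd"])
                names.append(c)
                out_tags.append(dict(tag))
            else:
                v = df[c].fillna(st["mode"])
                cats = st["categories"]
                if len(cats) <= 2:
                    out_cols.append((v == cats[-1]).to_numpy(dtype=np.float64))
                    names.append(c)
                    out_tags.append(dict(tag))
                else:
                    for cat in cats:
                        out_cols.append((v == cat).to_numpy(dtype=np.float64))
                        names.append(f"{c}={cat}")
                        out_tags.append(dict(tag))
        return np.column_stack(out_cols), names, out_tags


def preprocess_structured(df: pd.DataFrame, tags: dict, train_idx: np.ndarray):
    """Convenience wrapper: fit on ``df.iloc[train_idx]``, transform all.

    Returns ``(X, column_names, column_tags, preprocessor)``.
    """
    pre = StructuredPreprocessor(tags).fit(df.iloc[train_idx])
    X, names, out_tags = pre.transform(df)
    return X, names, out_tags, pre


def impute(df: pd.DataFrame, strategy: str, train_idx: np.ndarray | None = None) -> pd.DataFrame:
    """Impute numeric columns with one of {mean, median, knn, iterative},
    fitting on the training rows only."""
    num_cols = [c for c in df.columns if pd.api.types.is_float_dtype(df[c])]
    if strategy in ("mean", "median"):
        imp = SimpleImputer(strategy=strategy)
    elif strategy == "knn":
        imp = KNNImputer(n_neighbors=5)
    elif strategy == "iterative":
        imp = IterativeImputer(max_iter=10, tol=1e-3, random_state=0)
    else:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    out = df.copy()
    if not num_cols:
        return out
    train = df[num_cols] if train_idx is None else df[num_cols].iloc[train_idx]
    imp.fit(train.to_numpy(dtype=np.float64))
    out[num_cols] = imp.transform(df[num_cols].to_numpy(dtype=np.float64))
    return out


# -- notes preprocessing -------------------------------------------------

def format_patient_notes(records: Sequence[dict],
                         note_types: Sequence[str] = NOTE_TYPES) -> str:
    """Prefix each note with its type ("Nursing: ...") and join all notes
    with a newline, in the fixed note-type order."""
    parts: list[str] = []
    for note_type in note_types:
        for rec in records:
            if rec["note_type"] == note_type:
                parts.append(f"{note_type}: {rec['text']}")
    return "\n".join(parts)


def tokenize(text: str) -> list[str]:
    """The stub provider's tokenizer: lowercase, split on whitespace."""
    return text.lower().split()


def _fix_length(tokens: list[str], max_tokens: int) -> list[str]:
    if len(tokens) >= max_tokens:
        return tokens[:max_tokens]
    return tokens + [PAD_TOKEN] * (max_tokens - len(tokens))


def preprocess_notes(
    records: Sequence[dict],
    ids: Sequence[str],
    groups: Sequence[str] = ("combined",),
    max_tokens: int = 512,
    note_types: Sequence[str] = NOTE_TYPES,
) -> dict[str, list[list[str]]]:
    """Fixed-length token sequences per patient.

    ``groups`` selects which views to build: "combined" concatenates all
    note types per patient; a note-type name builds that type's notes
    only (used by the data-sources partition).  Patients with no notes
    get all-padding sequences.
    """
    by_patient: dict[str, list[dict]] = {pid: [] for pid in ids}
    for rec in records:
        by_patient[rec["patient_id"]].append(rec)
    out: dict[str, list[list[str]]] = {}
    for group in groups:
        if group == "combined":
            selected = note_types
        elif group in note_types:
            selected = (group,)
        else:
            raise ValueError(f"unknown note group {group!r}")
        seqs = []
        for pid in ids:
            text = format_patient_notes(by_patient[pid], selected)
            seqs.append(_fix_length(tokenize(text), max_tokens))
        out[group] = seqs
    return out


def label_plos(lengths_of_stay_days) -> np.ndarray:
    """Prolonged length of stay: 1 iff the stay strictly exceeds 7 days."""
    days = np.asarray(lengths_of_stay_days, dtype=np.float64)
    if (days < 0).any():
        raise ValueError("lengths of stay must be non-negative")
    return (days > 7.0).astype(int)


# -- canonical on-disk formats -------------------------------------------

def write_cohort(raw: RawCohort, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw.structured.to_csv(outdir / "structured.csv")
    (outdir / "tags.json").write_text(json.dumps(raw.tags, indent=2))
    with open(outdir / "notes.jsonl", "w") as fh:
        for rec in raw.notes:
            fh.write(json.dumps(rec) + "\n")
    pd.DataFrame({"patient_id": raw.ids, "label": raw.labels}).to_csv(
        outdir / "labels.csv", index=False
    )


def read_cohort(indir) -> RawCohort:
    indir = Path(indir)
    structured = pd.read_csv(indir / "structured.csv", index_col="patient_id")
    tags = json.loads((indir / "tags.json").read_text())
    # restore string dtype for categorical columns read as objects/floats
    notes = [json.loads(line) for line in (indir / "notes.jsonl").read_text().splitlines()]
    lab = pd.read_csv(indir / "labels.csv")
    labels = lab["label"].to_numpy(dtype=int)
    ids = lab["patient_id"].astype(str).tolist()
    structured = structured.loc[ids]
    return RawCohort(structured=structured, tags=tags, notes=notes, labels=labels, ids=ids)


def cohort_variant(spec: CohortSpec, **changes) -> CohortSpec:
    """A copy of ``spec`` with the given fields replaced."""
    return replace(spec, **changes)
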