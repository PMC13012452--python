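"""Cross-modal projection of encoder features into a language-model
embedding space, plus multimodal prompt assembly.

The projector is a two-layer MLP applied row-wise to a feature matrix E of
shape L x D_feat:

    P = Dropout(ReLU(E W1 + b1)) W2 + b2

where W1 maps D_feat -> D_LLM and W2 refines within D_LLM.  Dropout is
active only in training mode; evaluation is deterministic.  Pre-training
minimises a mean-squared alignment loss against target embedding sequences
produced by a pluggable text-embedding function, with the upstream encoder
frozen — the desk-scale analogue of aligning signal features with the
embedding of a curve-morphology description.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "ProjectorParams",
    "ProjectorConfig",
    "PromptBundle",
    "project",
    "pretrain_projector",
    "build_prompt",
    "mask_pft_text",
    "PFT_BLOCK_HEADER",
]


@dataclass
class ProjectorParams:
    """Learnable parameters {W1, b1, W2, b2} with a dropout rate."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    dropout_rate: float = 0.1

    @classmethod
    def init(cls, d_feat: int, d_llm: int, seed=0, dropout_rate: float = 0.1):
        rng = np.random.default_rng(seed)
        return cls(
            W1=rng.normal(0.0, np.sqrt(2.0 / d_feat), size=(d_feat, d_llm)),
            b1=np.zeros(d_llm),
            W2=rng.normal(0.0, np.sqrt(1.0 / d_llm), size=(d_llm, d_llm)),
            b2=np.zeros(d_llm),
            dropout_rate=dropout_rate,
        )

    @property
    def d_feat(self) -> int:
        return self.W1.shape[0]

    @property
    def d_llm(self) -> int:
        return self.W1.shape[1]


@dataclass(frozen=True)
class ProjectorConfig:
    d_llm: int = 256
    dropout_rate: float = 0.1
    lr: float = 1e-3
    epochs: int = 200
    seed: int = 0


def project(
    e: np.ndarray,
    params: ProjectorParams,
    mode: str = "eval",
    rng=None,
) -> np.ndarray:
    """Row-wise affine -> ReLU -> dropout (train only) -> affine."""
    e = np.asarray(e, dtype=float)
    if e.shape[-1] != params.d_feat:
        raise ValueError(
            f"feature width {e.shape[-1]} != projector D_feat {params.d_feat}"
        )
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    h = np.maximum(e @ params.W1 + params.b1, 0.0)
    if mode == "train" and params.dropout_rate > 0:
        rng = np.random.default_rng(rng) if not isinstance(
            rng, np.random.Generator
        ) else rng
        keep = 1.0 - params.dropout_rate
        h = h * (rng.random(h.shape) < keep) / keep
    return h @ params.W2 + params.b2


def pretrain_projector(
    pairs: list,
    config: ProjectorConfig | None = None,
    params: ProjectorParams | None = None,
) -> tuple:
    """Fit the projector to (E_i, target embedding sequence) pairs by MSE.

    The encoder outputs are treated as fixed inputs (frozen upstream);
    dropout is disabled during this deterministic fit so the loss trajectory
    is reproducible by seed.  Returns (params, loss_history).
    """
    if not pairs:
        raise ValueError("no training pairs")
    config = config or ProjectorConfig()
    d_feat = pairs[0][0].shape[1]
    d_llm = pairs[0][1].shape[1]
    for e, t in pairs:
        if e.shape[0] != t.shape[0] or e.shape[1] != d_feat or t.shape[1] != d_llm:
            raise ValueError("inconsistent widths in training pairs")
    params = params or ProjectorParams.init(
        d_feat, d_llm, seed=config.seed, dropout_rate=config.dropout_rate
    )
    e_all = np.concatenate([p[0] for p in pairs], axis=0)
    t_all = np.concatenate([p[1] for p in pairs], axis=0)
    n = e_all.shape[0]
    tree = {"W1": params.W1, "b1": params.b1, "W2": params.W2, "b2": params.b2}
    opt = nn.Adam(tree, lr=config.lr)
    history = []
    for _ in range(config.epochs):
        pre = e_all @ params.W1 + params.b1
        h = np.maximum(pre, 0.0)
        out = h @ params.W2 + params.b2
        diff = out - t_all
        loss = float(np.mean(diff**2))
        history.append(loss)
        dout = 2.0 * diff / diff.size
        grads = {
            "W2": h.T @ dout,
            "b2": dout.sum(axis=0),
        }
        dh = dout @ params.W2.T
        dpre = dh * (pre > 0)
        grads["W1"] = e_all.T @ dpre
        grads["b1"] = dpre.sum(axis=0)
        opt.step(grads)
    return params, history


# ---------------------------------------------------------------------------
# prompt assembly
# ---------------------------------------------------------------------------

PFT_BLOCK_HEADER = "## Pulmonary function results"
_MASK_TOKEN = "[withheld]"

#: indices rendered in the PFT block, in display order
_PROMPT_INDICES = ("FEV1", "FVC", "FEV1_FVC", "PEF", "FEF25_75")
_DISPLAY = {
    "FEV1": ("FEV1", "L"),
    "FVC": ("FVC", "L"),
    "FEV1_FVC": ("FEV1/FVC", ""),
    "PEF": ("PEF", "L/s"),
    "FEF25_75": ("FEF25-75", "L/s"),
}


@dataclass
class PromptBundle:
    """Structured prompt text plus optional projected embeddings."""

    text: str
    embeddings: np.ndarray | None = None
    mask_flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "text": self.text,
            "has_embeddings": self.embeddings is not None,
            "mask_flags": dict(self.mask_flags),
        }


def _fmt(value, unit, ratio=False) -> str:
    if value is None:
        return "not available"
    s = f"{value:.3f}" if ratio else f"{value:.2f}"
    return f"{s} {unit}".strip()


def _pft_block(pft) -> str:
    lines = [PFT_BLOCK_HEADER]
    for name in _PROMPT_INDICES:
        label, unit = _DISPLAY[name]
        idx = pft.indices.get(name) if pft is not None else None
        if idx is None:
            continue
        ratio = name == "FEV1_FVC"
        z = f"{idx.z_score:+.2f}" if idx.z_score is not None else "n/a"
        lines.append(
            f"- {label}: measured {_fmt(idx.measured, unit, ratio)}, "
            f"predicted {_fmt(idx.predicted, unit, ratio)}, "
            f"LLN {_fmt(idx.lln, unit, ratio)}, z-score {z}"
        )
    return "\n".join(lines)


def mask_pft_text(text: str) -> str:
    """Replace every numeric token inside the PFT block with a mask token,
    preserving section headers and line structure.  Idempotent."""
    lines = text.split("\n")
    out, in_block = [], False
    for line in lines:
        if line.startswith("## "):
            in_block = line.strip() == PFT_BLOCK_HEADER
            out.append(line)
            continue
        if in_block:
            line = re.sub(r"[-+]?\d+(?:\.\d+)?", _MASK_TOKEN, line)
            # collapse unit remnants left dangling after masked numbers
            line = re.sub(r"\[withheld\]\s*(?:L/s|L|%)", _MASK_TOKEN, line)
        out.append(line)
    return "\n".join(out)


def build_prompt(
    record,
    pft,
    copd_prob: float | None = None,
    projected: np.ndarray | None = None,
    mask_pft: bool = False,
) -> PromptBundle:
    """Assemble the three-block multimodal prompt.

    Blocks: demographics, PFT results (measured / predicted / LLN / z-score
    for FEV1, FVC, FEV1/FVC, PEF, FEF25-75), and the encoder's COPD
    probability; an embedding placeholder span is appended when projected
    embeddings are attached.  ``mask_pft`` withholds every numeric PFT token
    while preserving the section header.
    """
    if pft is None and not mask_pft:
        raise ValueError("pft is required unless mask_pft is set")
    d = record.demographics
    demo_block = (
        "## Patient information\n"
        f"- Age: {d.age:.0f} years\n"
        f"- Sex: {d.sex}\n"
        f"- Height: {d.height:.0f} cm\n"
        f"- Smoking status: {d.smoking}"
    )
    pft_block = _pft_block(pft)
    if mask_pft:
        pft_block = mask_pft_text(pft_block)
    parts = [demo_block, pft_block]
    if copd_prob is not None:
        parts.append(
            "## Signal model output\n"
            f"- Curve-encoder COPD probability: {copd_prob:.3f}"
        )
    if projected is not None:
        parts.append(
            "## Curve embedding\n"
            f"<curve_embedding tokens={projected.shape[0]}>"
        )
    return PromptBundle(
        text="\n\n".join(parts),
        embeddings=projected,
        mask_flags={"pft": bool(mask_pft)},
    )
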