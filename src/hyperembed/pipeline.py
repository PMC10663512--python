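"""End-to-end embedding pipeline.

Chains the four stages: (1) hidden-degree and inverse-temperature inference,
(2) model-corrected Laplacian Eigenmaps initialization, (3) likelihood
refinement of positions, (4) final per-node hidden-degree adjustment.
"""

from __future__ import annotations

import logging

import numpy as np

from .eigenmaps import initial_positions
from .geometry import ModelParams
from .inference import InferenceConfig, NetworkData, fit_hidden_degrees, infer_beta
from .likelihood import (
    EmbeddingResult,
    MLEConfig,
    final_degree_adjustment,
    refine_positions,
)

logger = logging.getLogger(__name__)

__all__ = ["embed_network"]


def embed_network(
    network: NetworkData,
    D: int,
    rng: np.random.Generator,
    beta: float | None = None,
    inference_config: InferenceConfig | None = None,
    mle_config: MLEConfig | None = None,
    refine_rounds: int = 1,
) -> EmbeddingResult:
    """Embed a connected simple graph on the D-sphere.

    ``beta=None`` infers the inverse temperature from the mean local
    clustering; passing a value fixes it (useful for controlled experiments).
    ``refine_rounds > 1`` alternates extra position-refinement rounds with
    hidden-degree readjustment, restarting each round from the previous
    maximum-likelihood output.  All randomness flows through ``rng``.
    """
    cfg = inference_config or InferenceConfig()
    mcfg = mle_config or MLEConfig()
    params = ModelParams.from_mean_degree(
        network.n_nodes, D, beta=D + 1.0, mean_degree=network.observed_mean_degree
    )

    if beta is None:
        logger.info("stage 1: inferring hidden degrees and beta")
        beta_hat, hidden, _mu = infer_beta(network, params, cfg, rng)
    else:
        logger.info("stage 1: fitting hidden degrees at fixed beta=%.4f", beta)
        beta_hat = float(beta)
        hidden = fit_hidden_degrees(network, beta_hat, params, cfg, rng)
    params = params.with_beta(beta_hat)

    logger.info("stage 2: Laplacian Eigenmaps initialization")
    pos0 = initial_positions(network, hidden, params, rng)

    pos = pos0
    trace: list = []
    for round_idx in range(max(refine_rounds, 1)):
        logger.info("stage 3 (round %d): likelihood refinement of positions", round_idx + 1)
        pos, round_trace = refine_positions(network, hidden, pos, params, mcfg, rng)
        trace.extend(round_trace)
        logger.info("stage 4 (round %d): hidden-degree adjustment", round_idx + 1)
        hidden, eps_max = final_degree_adjustment(network, hidden, pos, params, cfg, rng)

    return EmbeddingResult(
        hidden_degrees=hidden,
        positions=pos,
        params=params,
        loglik_trace=trace,
        eps_max=eps_max,
    )
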