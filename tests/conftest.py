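import pytest
import sympy as sp

from nhpm import example1, example3, solve_coefficients


@pytest.fixture(scope="session")
def ex1_printed():
    return solve_coefficients(example1(), 5, mode="as_printed")


@pytest.fixture(scope="session")
def ex1_strict():
    return solve_coefficients(example1(), 5, mode="strict")


@pytest.fixture(scope="session")
def ex3_strict():
    return solve_coefficients(example3(), 5, mode="strict")


@pytest.fixture(scope="session")
def ex1_alpha1_printed():
    return solve_coefficients(example1(alpha=sp.Integer(1)), 8, mode="as_printed")
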