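import pytest

import solutherm as st

# Central values of the published solution-thermodynamics table for the
# sulfamerazine MeCN/EtOH study (21 compositions at Thm = 297.6 K), used both
# as regression targets and as input for the compensation golden test.
TABLE3_DG = [19.83, 19.6, 19.3, 19.09, 18.85, 18.58, 18.35, 18.08, 17.84,
             17.58, 17.35, 17.09, 16.84, 16.58, 16.34, 16.09, 15.83, 15.58,
             15.33, 15.07, 14.8]
TABLE3_DH = [31.15, 31.2, 30.79, 30.44, 30.35, 29.95, 30.0, 29.3, 28.9, 28.9,
             28.6, 28.6, 28.3, 27.8, 27.7, 27.7, 27.4, 26.9, 26.7, 26.7, 26.2]
TABLE3_DS = [38.0, 39.0, 38.5, 38.1, 38.7, 38.2, 39.1, 37.6, 37.3, 38.0, 37.7,
             38.6, 38.4, 37.7, 38.1, 39.0, 38.8, 38.0, 38.1, 39.1, 38.1]
TABLE3_ZETA_H = [0.733, 0.729, 0.729, 0.728, 0.725, 0.725, 0.721, 0.723,
                 0.723, 0.719, 0.718, 0.713, 0.712, 0.713, 0.709, 0.705,
                 0.703, 0.704, 0.702, 0.697, 0.698]
# Published mixing-functions table (same compositions, same Thm).
TABLE4_DG_MIX = [6.9, 6.7, 6.4, 6.2, 5.92, 5.7, 5.4, 5.15, 4.91, 4.65, 4.42,
                 4.16, 3.91, 3.65, 3.41, 3.16, 2.9, 2.66, 2.4, 2.14, 1.91]
TABLE4_DH_MIX = [7.00, 7.1, 6.6, 6.3, 6.21, 5.8, 5.8, 5.1, 4.8, 4.7, 4.4, 4.4,
                 4.1, 3.6, 3.5, 3.6, 3.2, 2.7, 2.5, 2.5, 2.0]
# Published four-parameter hybrid-model coefficients.
EQ13 = dict(a1=5.086, m1=-3260.9, a2=4.664, m2=-3773.8)


@pytest.fixture(scope="session")
def paper_grid() -> st.SolubilityGrid:
    return st.load_sulfamerazine()


@pytest.fixture(scope="session")
def fusion() -> st.FusionProperties:
    return st.FusionProperties(dH_fus=41.3, Tm=508.5)


@pytest.fixture(scope="session")
def analysis(paper_grid) -> st.SolutionAnalysis:
    return st.analyze_grid(paper_grid)
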