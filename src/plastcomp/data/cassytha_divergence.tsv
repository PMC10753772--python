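	OR766695	OR766693	OR766694	OR766692	OR766690	OR766691	OR766688	OR766689
OR766695	0	0.000139	0.000304	0.000715	0.005778	0.005796	0.005831	0.005812
OR766693	0.000139	0	0.000218	0.000628	0.005691	0.005708	0.005769	0.005751
OR766694	0.000304	0.000218	0	0.000663	0.005761	0.005777	0.005839	0.005821
OR766692	0.000715	0.000628	0.000663	0	0.005325	0.005343	0.005435	0.005418
OR766690	0.005778	0.005691	0.005761	0.005325	0	0.000017	0.000951	0.000932
OR766691	0.005796	0.005708	0.005777	0.005343	0.000017	0	0.000967	0.000951
OR766688	0.005831	0.005769	0.005839	0.005435	0.000951	0.000967	0	0.000017
OR766689	0.005812	0.005751	0.005821	0.005418	0.000932	0.000951	0.000017	0
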