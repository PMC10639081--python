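channel	syn_background	syn_mmrd	syn_oxygen
A[C>A]A	0.014448936	0.0014089732	0
A[C>A]C	0.015003138	0.00083129909	0
A[C>A]G	0.0058692244	0.0011506871	0
A[C>A]T	0.013685039	0.00098500262	0
C[C>A]A	0.018389477	0.00033472612	0
C[C>A]C	0.012716521	0.001567906	0
C[C>A]G	0.0066256037	0.0009560868	0
C[C>A]T	0.010359738	0.0034497921	0
G[C>A]A	0.0059110318	0.0013951495	0
G[C>A]C	0.006132078	0.00069468171	0
G[C>A]G	0.013872681	0.0020007685	0
G[C>A]T	0.008338985	0.0019450904	0
T[C>A]A	0.0080577309	0.00060826888	0
T[C>A]C	0.0079139072	0.0012054495	0
T[C>A]G	0.0093848551	0.00027948302	0
T[C>A]T	0.0086743828	0.0037311841	0
A[C>G]A	0.010389176	0.0016367625	0
A[C>G]C	0.011028394	0.0024389166	0
A[C>G]G	0.0079288185	0.000297257	0
A[C>G]T	0.0087693717	0.0019087454	0
C[C>G]A	0.015312215	0.0018698134	0
C[C>G]C	0.0088193149	0.0019534282	0
C[C>G]G	0.0042498201	0.0039101968	0
C[C>G]T	0.0064679718	0.00029719476	0
G[C>G]A	0.018596824	0.0035787311	0
G[C>G]C	0.0065735614	0.00033693433	0
G[C>G]G	0.013243749	0.0011438324	0
G[C>G]T	0.010243204	0.00042068127	0
T[C>G]A	0.015575579	0.0030216372	0
T[C>G]C	0.0073144833	0.0013526849	0
T[C>G]G	0.012560063	0.0014168123	0
T[C>G]T	0.0080969891	0.0024347272	0
A[C>T]A	0.0080277826	0.011254666	0
A[C>T]C	0.0086089338	0.053724639	0
A[C>T]G	0.0075101452	0.033163963	0
A[C>T]T	0.011792446	0.02505512	0
C[C>T]A	0.0074301071	0.027823938	0
C[C>T]C	0.019294248	0.027702026	0
C[C>T]G	0.012288376	0.029546377	0
C[C>T]T	0.01457366	0.027144333	0
G[C>T]A	0.0080964221	0.043672123	0
G[C>T]C	0.00924984	0.045354433	0
G[C>T]G	0.01089194	0.04196688	0
G[C>T]T	0.010721307	0.024349537	0
T[C>T]A	0.0083115462	0.011009526	0
T[C>T]C	0.013791804	0.029602488	0
T[C>T]G	0.011563988	0.017081822	0
T[C>T]T	0.010264877	0.014421929	0
A[T>A]A	0.0060372666	0.0028722601	0
A[T>A]C	0.011814674	0.00066548521	0
A[T>A]G	0.011974644	0.0010158047	0
A[T>A]T	0.0073771561	0.0018693913	0
C[T>A]A	0.003474411	0.00095365582	0
C[T>A]C	0.0090127954	0.0011925706	0
C[T>A]G	0.021313514	0.0014712704	0
C[T>A]T	0.0100972	0.00088047007	0
G[T>A]A	0.011995319	0.00090987461	0
G[T>A]C	0.0085580377	0.00093674622	0
G[T>A]G	0.0097168889	0.001678557	0
G[T>A]T	0.010795603	0.0015162854	0
T[T>A]A	0.010877841	0.0031433744	0
T[T>A]C	0.011741765	0.00059512376	0
T[T>A]G	0.0049308112	0.0010172462	0
T[T>A]T	0.011502839	0.00016848211	0
A[T>C]A	0.0075168022	0.014340275	0.18
A[T>C]C	0.010012409	0.026844957	0.023333333
A[T>C]G	0.012178861	0.049251543	0.023333333
A[T>C]T	0.010604688	0.025158688	0.023333333
C[T>C]A	0.0075198653	0.025590048	0.023333333
C[T>C]C	0.0036834486	0.020927988	0.023333333
C[T>C]G	0.011132247	0.021824798	0.023333333
C[T>C]T	0.011733106	0.015344108	0.023333333
G[T>C]A	0.016892487	0.026594233	0.18
G[T>C]C	0.0093702739	0.029088326	0.023333333
G[T>C]G	0.010519662	0.016789241	0.023333333
G[T>C]T	0.012591716	0.054734569	0.18
T[T>C]A	0.0055407722	0.026581099	0.18
T[T>C]C	0.0079791203	0.024490133	0.023333333
T[T>C]G	0.01239893	0.033420483	0.023333333
T[T>C]T	0.019377802	0.033752628	0.023333333
A[T>G]A	0.010298148	0.00084083268	0
A[T>G]C	0.021888893	0.0014328799	0
A[T>G]G	0.014084486	0.0023094499	0
A[T>G]T	0.012391084	0.0021910776	0
C[T>G]A	0.0055370099	0.00049140641	0
C[T>G]C	0.011781035	0.0029206342	0
C[T>G]G	0.0079954502	0.0010298066	0
C[T>G]T	0.01142381	0.0028787272	0
G[T>G]A	0.010244162	8.8351923e-05	0
G[T>G]C	0.012759398	0.00064257183	0
G[T>G]G	0.0050223062	0.0011467385	0
G[T>G]T	0.0067461047	0.000797786	0
T[T>G]A	0.0076377993	0.00054279515	0
T[T>G]C	0.0091800606	0.0015930902	0
T[T>G]G	0.012987727	0.0011813129	0
T[T>G]T	0.0067792819	0.00085611902	0
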