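case,gesture,muscle,without,with
1,kiss,orbicularis,42,40
1,kiss,buccinator,29,14
1,kiss,frontalis,20,4
1,smile,orbicularis,18,19
1,smile,buccinator,9,11
1,smile,frontalis,,
1,eyebrows,orbicularis,,
1,eyebrows,buccinator,,
1,eyebrows,frontalis,,
2,kiss,orbicularis,10,33
2,kiss,buccinator,7,8
2,kiss,frontalis,,
2,smile,orbicularis,32,10
2,smile,buccinator,8,8
2,smile,frontalis,,
2,eyebrows,orbicularis,32,10
2,eyebrows,buccinator,,
2,eyebrows,frontalis,57,64
3,kiss,orbicularis,12,11
3,kiss,buccinator,12,12
3,kiss,frontalis,3,3
3,smile,orbicularis,6,8
3,smile,buccinator,23,22
3,smile,frontalis,4,5
3,eyebrows,orbicularis,5,7
3,eyebrows,buccinator,10,18
3,eyebrows,frontalis,5,5
4,kiss,orbicularis,5,5
4,kiss,buccinator,4,5
4,kiss,frontalis,2,2
4,smile,orbicularis,3,3
4,smile,buccinator,5,4
4,smile,frontalis,3,3
4,eyebrows,orbicularis,4,4
4,eyebrows,buccinator,2,2
4,eyebrows,frontalis,4,3
5,kiss,orbicularis,23,21
5,kiss,buccinator,7,5
5,kiss,frontalis,7,5
5,smile,orbicularis,14,12
5,smile,buccinator,11,9
5,smile,frontalis,6,7
5,eyebrows,orbicularis,13,10
5,eyebrows,buccinator,9,8
5,eyebrows,frontalis,6,5
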