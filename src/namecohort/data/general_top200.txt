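# 200 most common surnames in the Ontario general population (on neither minority list)
Smith
Brown
Lee
Wilson
Martin
Taylor
Campbell
Williams
Thompson
Jones
Adams
Ahmed
Alexander
Ali
Allen
Anderson
Andrews
Armstrong
Bailey
Baker
Barnes
Bélanger
Bell
Bennett
Black
Boyd
Bradley
Brooks
Burke
Burns
Butler
Cameron
Carter
Chapman
Choi
Clark
Clarke
Cole
Collins
Cook
Cooper
Cox
Craig
Crawford
Cunningham
Da Silva
Davidson
Davies
Davis
Dawson
Dixon
Douglas
Doyle
Duncan
Dunn
Edwards
Elliott
Ellis
Evans
Ferguson
Fernandes
Ferreira
Fisher
Fleming
Ford
Foster
Fox
Francis
Fraser
Gagnon
Garcia
Gauthier
George
Gibson
Gill
Gordon
Graham
Grant
Gray
Green
Hall
Hamilton
Harris
Harrison
Hart
Harvey
Hassan
Hayes
Henderson
Henry
Hill
Holmes
Howard
Hughes
Hunt
Hunter
Huynh
Jackson
James
Johnson
Johnston
Kelly
Kennedy
Kerr
Khan
Kim
King
Knight
Lalonde
Lawrence
Le
Leblanc
Lewis
Little
Macdonald
Mackenzie
Maclean
Macleod
Mann
Marshall
Mason
Matthews
McDonald
McIntyre
McKay
McKenzie
McLean
McLeod
Miller
Mills
Mitchell
Mohamed
Moore
Morgan
Morin
Morris
Morrison
Murphy
Murray
Nelson
Nguyen
O'Brien
Palmer
Park
Parker
Parsons
Patterson
Paul
Payne
Pereira
Perry
Peters
Phillips
Porter
Powell
Price
Reid
Reynolds
Richards
Richardson
Roberts
Robertson
Robinson
Rogers
Rose
Ross
Roy
Russell
Ryan
Santos
Saunders
Scott
Seguin
Shah
Shaw
Silva
Simpson
Spencer
Stevens
Stevenson
Stewart
Sullivan
Sutherland
Thomas
Thomson
Tran
Tremblay
Turner
Walker
Wallace
Walsh
Ward
Warren
Watson
White
Williamson
Wood
Woods
Wright
Young
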